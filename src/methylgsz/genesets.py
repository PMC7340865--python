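"""Gene set collections and GMT input/output.

GMT is the tab-separated format used by MSigDB-style databases: one set per
line as ``name<TAB>description<TAB>member<TAB>member...``. Duplicate members
within a set are collapsed on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataset import DataError


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text category labels.

    ``sets`` maps set name -> member symbols (duplicates collapsed,
    insertion order kept); ``categories`` maps set name -> category label
    (e.g. "GO-MF"), used for per-category FDR when present.
    """

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: list(dict.fromkeys(members)) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}

    def category(self, name: str) -> str:
        return self.categories.get(name, "")

    @classmethod
    def read_gmt(cls, path, category: str | None = None) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise DataError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
                name, desc, *members = parts
                if name in sets:
                    raise DataError(f"{path}:{ln}: duplicate set name {name!r}")
                sets[name] = list(dict.fromkeys(m for m in members if m))
                descriptions[name] = desc
        cats = {name: category for name in sets} if category else {}
        return cls(sets, categories=cats, descriptions=descriptions)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *members]) + "\n")
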