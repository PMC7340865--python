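"""Core data containers: methylation matrix, probe annotation, sample sheet.

The central object is :class:`MethylationDataset`, which joins a probes x
samples beta-value matrix with an Illumina-manifest-style probe annotation
and a per-sample covariate sheet. All downstream stages (probe filtering,
per-CpG regression, gene scoring, region summaries) operate on this object.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gene-region categories relative to a gene model on the 450K manifest.
GENE_REGION_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")

#: Probe position relative to the nearest CpG island.
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Leukocyte cell types whose proportions enter the regression models.
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: Manifest column names accepted on annotation TSVs.
ANNOTATION_COLUMNS = {
    "IlmnID": "probe_id",
    "CHR": "chromosome",
    "MAPINFO": "position",
    "UCSC_RefGene_Name": "gene_names",
    "UCSC_RefGene_Group": "gene_region_groups",
    "Relation_to_UCSC_CpG_Island": "island_relation",
}


class DataError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation (manifest semantics).

    ``table`` is indexed by probe id with columns ``chromosome`` (labels
    "1".."22", "X", "Y"), ``position`` (1-based), ``gene_names`` and
    ``gene_region_groups`` (semicolon-joined, parallel, possibly empty) and
    ``island_relation`` (one of :data:`ISLAND_RELATIONS`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"chromosome", "position", "gene_names", "gene_region_groups",
                   "island_relation"} - set(self.table.columns)
        if missing:
            raise DataError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise DataError("duplicate probe ids in annotation")
        bad = set(self.table["island_relation"]) - set(ISLAND_RELATIONS)
        if bad:
            raise DataError(f"unknown island relations: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table.loc[probe_ids])

    @classmethod
    def read_tsv(cls, path) -> "ProbeAnnotation":
        """Read an Illumina-manifest-style annotation TSV.

        Accepts manifest column names (IlmnID, CHR, MAPINFO, ...) or the
        internal names; CHR values with or without a "chr" prefix.
        """
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        raw = raw.rename(columns=ANNOTATION_COLUMNS)
        tab = raw.set_index("probe_id")
        tab["chromosome"] = [re.sub(r"^chr", "", c) for c in tab["chromosome"]]
        tab["position"] = tab["position"].astype(int)
        return cls(tab)

    def write_tsv(self, path) -> None:
        out = self.table.reset_index()
        out.columns = [
            {v: k for k, v in ANNOTATION_COLUMNS.items()}.get(c, c) for c in out.columns
        ]
        out.to_csv(path, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Per-sample covariates.

    Indexed by sample id. Required columns: ``smoking`` (1 = active smoker,
    0 = never smoker), ``age`` (years), ``sex`` (1 = male, 0 = female),
    ``bmi`` (kg/m^2), the six cell-type proportion columns
    (:data:`CELL_TYPES`, non-negative, summing to 1 per sample), ``chip``
    and ``array_pos`` (categorical technical covariates). Optional columns
    ``alcohol`` (units/week) and ``ses`` (manual / lower non-manual / upper
    non-manual) may contain missing values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"smoking", "age", "sex", "bmi", "chip", "array_pos", *CELL_TYPES}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["smoking"].isna().any():
            raise DataError("smoking status must be non-missing for every sample")
        props = self.table[list(CELL_TYPES)].to_numpy(float)
        if (props < 0).any():
            raise DataError("negative cell-type proportion")
        if not np.allclose(props.sum(axis=1), 1.0, atol=1e-6):
            raise DataError("cell-type proportions must sum to 1 (+/- 1e-6)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @classmethod
    def read_csv(cls, path) -> "SampleSheet":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def write_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass
class MethylationDataset:
    """Beta-value matrix joined with probe annotation and sample sheet."""

    beta: pd.DataFrame  # probes x samples, values in (0, 1)
    annotation: ProbeAnnotation
    sample_sheet: SampleSheet

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates or self.beta.columns.has_duplicates:
            raise DataError("duplicate probe or sample ids in beta matrix")
        if not self.beta.index.isin(self.annotation.probe_ids).all():
            raise DataError("annotation does not cover every probe in the beta matrix")
        if not self.beta.columns.equals(self.sample_sheet.sample_ids):
            raise DataError("beta matrix columns do not match sample sheet ids")
        vals = self.beta.to_numpy()
        if not ((vals > 0) & (vals < 1)).all():
            raise DataError("beta values must lie strictly inside (0, 1)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def probe_annotation(self) -> pd.DataFrame:
        """Annotation rows aligned to the beta matrix's probe order."""
        return self.annotation.table.loc[self.beta.index]

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        return MethylationDataset(
            self.beta.loc[probe_ids], self.annotation.subset(probe_ids), self.sample_sheet
        )

    @classmethod
    def from_files(cls, beta_path, annotation_path, sample_sheet_path) -> "MethylationDataset":
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        ann = ProbeAnnotation.read_tsv(annotation_path)
        sheet = SampleSheet.read_csv(sample_sheet_path)
        return cls(beta, ann.subset(beta.index), sheet)

    def write(self, beta_path, annotation_path=None, sample_sheet_path=None) -> None:
        self.beta.to_csv(beta_path, sep="\t")
        if annotation_path is not None:
            self.annotation.write_tsv(annotation_path)
        if sample_sheet_path is not None:
            self.sample_sheet.write_csv(sample_sheet_path)


def split_multi(field_value: str) -> list[str]:
    """Split a semicolon-joined manifest field into its entries."""
    if not field_value or (isinstance(field_value, float) and np.isnan(field_value)):
        return []
    return [x for x in str(field_value).split(";") if x]
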