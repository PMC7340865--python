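"""Collapse per-CpG statistics to one signed score per gene.

A gene's score is the t-statistic of its proxy CpG — the probe annotated to
the gene (at any gene-region group) with the maximum absolute t. The sign is
preserved, so the score carries the direction of the methylation change.
"""

from __future__ import annotations

import logging

import pandas as pd

from .dataset import ProbeAnnotation, split_multi

logger = logging.getLogger(__name__)


def map_probes_to_genes(annotation: ProbeAnnotation) -> dict[str, list[str]]:
    """Gene symbol -> list of probe ids annotated to it.

    A probe whose gene field lists k distinct symbols contributes to all k
    genes; repeated symbols within one probe's field (multiple transcript
    regions of the same gene) are de-duplicated. Probes with an empty gene
    field are excluded.
    """
    mapping: dict[str, list[str]] = {}
    for probe_id, genes in annotation.table["gene_names"].items():
        for gene in dict.fromkeys(split_multi(genes)):  # order-preserving de-dup
            mapping.setdefault(gene, []).append(probe_id)
    return mapping


def gene_proxy_scores(ewas_table: pd.DataFrame, gene_map: dict[str, list[str]]) -> pd.DataFrame:
    """Per-gene signed proxy score table.

    ``ewas_table`` must be indexed by probe id with columns ``t`` and ``p``.
    For each gene the proxy is the probe maximizing |t|; ties are broken by
    smaller p, then lexicographically smaller probe id, so the result is
    deterministic. Genes whose probes were all filtered out of the EWAS are
    omitted (counted in the log).

    Returns a DataFrame indexed by gene with columns
    ``score, proxy_probe_id, n_probes, best_p``.
    """
    t = ewas_table["t"]
    p = ewas_table["p"]
    rows = []
    n_dropped = 0
    for gene, probes in gene_map.items():
        present = [pid for pid in probes if pid in t.index and pd.notna(t.loc[pid])]
        if not present:
            n_dropped += 1
            continue
        # max |t|, ties -> smaller p, then smaller probe id
        best = min(present, key=lambda pid: (-abs(t.loc[pid]), p.loc[pid], pid))
        rows.append((gene, float(t.loc[best]), best, len(present), float(p.loc[best])))
    if n_dropped:
        logger.info("gene scoring: %d gene(s) had no surviving probes", n_dropped)
    out = pd.DataFrame(rows, columns=["gene", "score", "proxy_probe_id", "n_probes", "best_p"])
    return out.set_index("gene").sort_index()


def write_gene_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t")


def read_gene_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
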