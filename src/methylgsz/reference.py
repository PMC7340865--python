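"""Bundled reference table of published smoking-associated CpG sites.

The table lists the 60 genome-wide-significant differentially methylated
CpGs from a published whole-blood 450K smoking EWAS (125 adults, 21 active
vs 104 never smokers; 429,773 autosomal probes after QC), with the printed
effect size, standard error, p-value and FDR per probe. It serves as an
offline fixture for checking the multiple-testing arithmetic: running
step-up BH on the printed p-values against the full autosomal test count
must reproduce the printed FDR column.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: Autosomal probes surviving QC in the reference study; the BH test count.
REFERENCE_M_TOTAL = 429_773


def load_published_smoking_cpgs() -> pd.DataFrame:
    """The bundled 60-row reference table, indexed by probe id."""
    path = resources.files("methylgsz.data") / "published_smoking_cpgs.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col="probe_id")


def recompute_reference_fdr(table: pd.DataFrame | None = None,
                            m_total: int = REFERENCE_M_TOTAL) -> pd.DataFrame:
    """Re-derive the FDR column of the reference table from its p-values.

    Valid because the 60 listed probes are the experiment's smallest
    p-values, so their ranks within the subset equal their genome-wide
    ranks. Returns the table with ``fdr_recomputed`` and
    ``fdr_rel_error`` columns appended.
    """
    from .ewas import bh_adjust

    tab = load_published_smoking_cpgs() if table is None else table.copy()
    q = bh_adjust(tab["p"].to_numpy(), m_total)
    tab["fdr_recomputed"] = q
    tab["fdr_rel_error"] = np.abs(q - tab["fdr"]) / tab["fdr"]
    return tab


def sign_discordant_count(table: pd.DataFrame | None = None) -> int:
    """Probes whose effect sign opposes the majority sign in the table."""
    tab = load_published_smoking_cpgs() if table is None else table
    signs = np.sign(tab["effect"].to_numpy())
    majority = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
    return int((signs == -majority).sum())
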