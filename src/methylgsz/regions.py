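"""Average methylation per genomic-region category and group comparison.

For every gene-region group (TSS200, TSS1500, 5'UTR, 1stExon, Body, 3'UTR)
and island-relation category (Island, Shore, Shelf, OpenSea — north/south
shores and shelves pooled), the mean beta-value across the category's
probes is computed per sample, and smokers are compared with never smokers
by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import GENE_REGION_GROUPS, DataError, MethylationDataset, split_multi
from .ewas import bh_adjust

#: Island relations collapse onto four categories.
ISLAND_COLLAPSE = {
    "Island": "Island",
    "N_Shore": "Shore", "S_Shore": "Shore",
    "N_Shelf": "Shelf", "S_Shelf": "Shelf",
    "OpenSea": "OpenSea",
}

REGION_ORDER = (*GENE_REGION_GROUPS, "Island", "Shore", "Shelf", "OpenSea")


def region_probe_map(ds: MethylationDataset) -> dict[str, list]:
    """Region category -> probe ids contributing to it.

    A probe contributes to exactly one island-relation category and to every
    distinct gene-region group it is annotated with (once each).
    """
    ann = ds.probe_annotation()
    out: dict[str, list] = {r: [] for r in REGION_ORDER}
    for probe_id, row in ann.iterrows():
        out[ISLAND_COLLAPSE[row["island_relation"]]].append(probe_id)
        for grp in dict.fromkeys(split_multi(row["gene_region_groups"])):
            if grp not in GENE_REGION_GROUPS:
                raise DataError(f"unknown gene-region group {grp!r} on {probe_id}")
            out[grp].append(probe_id)
    return out


def region_means(ds: MethylationDataset) -> pd.DataFrame:
    """Per-sample mean beta within each region category (regions x samples).

    Categories with zero probes are omitted with a warning.
    """
    pmap = region_probe_map(ds)
    rows = {}
    for region in REGION_ORDER:
        probes = pmap[region]
        if not probes:
            warnings.warn(f"region {region!r} has no probes; omitted")
            continue
        rows[region] = ds.beta.loc[probes].mean(axis=0)
    return pd.DataFrame(rows).T


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first group (midranks on ties). ``mode`` is
    "exact" (enumeration; valid only without ties), "normal" (tie-corrected
    normal approximation with continuity correction) or "auto" (exact when
    n_x + n_y <= 25 and tie-free, else normal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return float(stats.rankdata(pooled)[: len(x)].sum()), 1.0
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 25 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        raise DataError("exact mode is not valid with ties")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    # U -> rank-sum of x
    W = float(res.statistic + len(x) * (len(x) + 1) / 2.0)
    return W, float(res.pvalue)


def region_analysis(ds: MethylationDataset) -> pd.DataFrame:
    """Smoker-vs-never comparison of per-sample region means.

    Returns one row per region: probe count, group medians, direction
    (sign of smoker median minus never median), W, nominal p, and a
    clearly-labelled BH column (the primary report is the nominal p).
    """
    smoking = ds.sample_sheet.table["smoking"].astype(int)
    if (smoking == 1).sum() == 0 or (smoking == 0).sum() == 0:
        raise DataError("need at least one smoker and one never smoker")
    means = region_means(ds)
    pmap = region_probe_map(ds)
    rows = []
    for region in means.index:
        vals = means.loc[region]
        smk = vals[smoking == 1].to_numpy()
        nvr = vals[smoking == 0].to_numpy()
        W, p = wilcoxon_rank_sum(smk, nvr)
        med_s, med_n = float(np.median(smk)), float(np.median(nvr))
        rows.append({
            "region": region, "n_probes": len(pmap[region]),
            "median_smoker": med_s, "median_never": med_n,
            "direction": int(np.sign(med_s - med_n)),
            "W": W, "p": p,
        })
    out = pd.DataFrame(rows).set_index("region")
    out["q_bh"] = bh_adjust(out["p"].to_numpy(), len(out))
    return out
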