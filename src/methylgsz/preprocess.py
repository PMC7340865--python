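"""Probe-level QC filters, beta/M conversion, control-probe batch PCs.

Filtering follows standard 450K practice: a probe is removed when its
detection p-value exceeds 0.01 in more than a small fraction of samples
(default 1%), when it maps to a sex chromosome, or when it appears on a
cross-reactive or SNP-affected blacklist. Regression runs on M-values,
M = log2(beta / (1 - beta)); batch structure is captured by the leading
principal components of the control-probe matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DataError, MethylationDataset

#: Clamp bound applied to beta before the logit transform; normalized
#: pipelines can emit boundary values, and the clamp bounds |M| at ~19.9.
BETA_CLAMP = 1e-6


def beta_to_m(beta, clamp: bool = True):
    """Convert beta-values in (0,1) to M-values, log2(beta/(1-beta)).

    Elementwise on arrays/DataFrames. With ``clamp`` (default) values are
    first clipped to [1e-6, 1-1e-6]; otherwise out-of-range input raises.
    """
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta
    if clamp:
        arr = np.clip(arr, BETA_CLAMP, 1.0 - BETA_CLAMP)
    else:
        vals = np.asarray(arr, dtype=float)
        if ((vals <= 0) | (vals >= 1)).any():
            bad = np.argwhere((vals <= 0) | (vals >= 1))
            raise DataError(f"beta value outside (0,1) at flat position(s) {bad[:5].tolist()}")
    return np.log2(arr / (1.0 - arr))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    vals = np.asarray(m, dtype=float)
    if not np.isfinite(vals).all():
        raise DataError("non-finite M-value")
    # expit in base 2, computed stably for large |M|
    out = 1.0 / (1.0 + np.exp2(-vals))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out if out.ndim else float(out)


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_probes` (applied in order)."""

    n_input: int
    n_detection: int
    n_sex_chromosome: int
    n_blacklist: int
    n_output: int
    n_blacklist_ids_not_in_data: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_probes(
    ds: MethylationDataset,
    detection_p: pd.DataFrame | None = None,
    crossreactive: list | None = None,
    snp_affected: list | None = None,
    detection_threshold: float = 0.01,
    max_failed_fraction: float = 0.01,
) -> tuple[MethylationDataset, FilterReport]:
    """Apply the probe-level QC filters, in order, preserving probe order.

    1. Remove probes whose detection p exceeds ``detection_threshold`` in
       more than ``max_failed_fraction`` of samples (kept if detected in
       >= 99% of samples under the defaults).
    2. Remove probes on chromosomes X and Y.
    3. Remove probes on either blacklist; blacklist ids absent from the
       dataset are counted and ignored, never an error.
    """
    probes = ds.probe_ids
    keep = pd.Series(True, index=probes)

    n_det = 0
    if detection_p is not None:
        if not detection_p.index.equals(ds.beta.index) or not detection_p.columns.equals(ds.beta.columns):
            raise DataError("detection-p matrix is not aligned to the beta matrix")
        failed_frac = (detection_p.to_numpy() > detection_threshold).mean(axis=1)
        det_fail = pd.Series(failed_frac > max_failed_fraction, index=probes)
        n_det = int(det_fail.sum())
        keep &= ~det_fail

    chrom = ds.probe_annotation()["chromosome"].astype(str)
    sex = keep & chrom.isin(["X", "Y"])
    n_sex = int(sex.sum())
    keep &= ~sex

    black = set(crossreactive or []) | set(snp_affected or [])
    n_absent = len(black - set(probes))
    bl = keep & probes.isin(black)
    n_bl = int(bl.sum())
    keep &= ~bl

    kept_ids = probes[keep]
    report = FilterReport(
        n_input=len(probes),
        n_detection=n_det,
        n_sex_chromosome=n_sex,
        n_blacklist=n_bl,
        n_output=len(kept_ids),
        n_blacklist_ids_not_in_data=n_absent,
    )
    if len(kept_ids) == 0:
        warnings.warn("all probes removed by QC filters; returning empty dataset")
        empty = MethylationDataset.__new__(MethylationDataset)
        empty.beta = ds.beta.loc[kept_ids]
        empty.annotation = ds.annotation.subset(kept_ids)
        empty.sample_sheet = ds.sample_sheet
        return empty, report
    return ds.subset_probes(kept_ids), report


def read_blacklist(path) -> list[str]:
    """Read a newline-delimited probe-id blacklist."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def control_probe_pcs(control: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """First ``k`` principal-component scores per sample of the control probes.

    ``control`` is control probes x samples. Samples are the observations:
    the transposed matrix is column-centered and decomposed by SVD. Sign
    convention: each component's loading vector has positive sum (flipped
    otherwise) so scores are reproducible across runs.

    If fewer than ``k`` non-degenerate components exist, the available ones
    are returned (zero columns for the rest) with a warning.
    """
    X = control.to_numpy(float).T  # samples x control probes
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    n_samples = X.shape[0]
    scores = np.zeros((n_samples, k))
    if rank < k:
        warnings.warn(f"control-probe matrix has rank {rank} < k={k}; "
                      "remaining components set to zero")
    for j in range(min(k, rank)):
        flip = -1.0 if Vt[j].sum() < 0 else 1.0
        scores[:, j] = flip * U[:, j] * s[j]
    return pd.DataFrame(scores, index=control.columns,
                        columns=[f"ctrl_pc{j + 1}" for j in range(k)])
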