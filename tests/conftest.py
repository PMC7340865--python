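import numpy as np
import pandas as pd
import pytest

from methylgsz.dataset import (CELL_TYPES, MethylationDataset, ProbeAnnotation,
                               SampleSheet)
from methylgsz.synthdata import SynthConfig, generate_dataset


def make_annotation(rows: dict) -> ProbeAnnotation:
    """Annotation from {probe_id: (chrom, pos, genes, groups, relation)}."""
    tab = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["chromosome", "position", "gene_names", "gene_region_groups",
                 "island_relation"],
    )
    tab.index.name = "probe_id"
    return ProbeAnnotation(tab)


def make_sheet(n: int, n_smokers: int, seed: int = 0, **extra) -> SampleSheet:
    rng = np.random.default_rng(seed)
    smoking = np.zeros(n, dtype=int)
    smoking[:n_smokers] = 1
    props = rng.dirichlet(np.ones(6) * 30, size=n)
    tab = pd.DataFrame({
        "smoking": smoking,
        "age": rng.uniform(40, 50, n),
        "sex": rng.integers(0, 2, n),
        "bmi": rng.normal(26, 4, n),
        **{ct: props[:, k] for k, ct in enumerate(CELL_TYPES)},
        "chip": ["chip1"] * n,
        "array_pos": ["pos1"] * n,
        **extra,
    }, index=[f"s{j}" for j in range(n)])
    tab.index.name = "sample_id"
    return SampleSheet(tab)


def make_dataset(beta: np.ndarray, annotation: ProbeAnnotation,
                 sheet: SampleSheet) -> MethylationDataset:
    frame = pd.DataFrame(beta, index=annotation.probe_ids,
                         columns=sheet.sample_ids)
    return MethylationDataset(frame, annotation, sheet)


@pytest.fixture(scope="session")
def small_synth():
    """Moderate synthetic dataset with planted effects (shared, read-only)."""
    cfg = SynthConfig(n_probes=3000, n_genes=800, n_sets=120,
                      set_size_range=(8, 25), seed=11)
    ds, control, truth = generate_dataset(cfg)
    return cfg, ds, control, truth


@pytest.fixture(scope="session")
def null_synth():
    """Synthetic dataset with all planted effects zeroed."""
    cfg = SynthConfig(n_probes=2500, n_genes=700, n_sets=100,
                      set_size_range=(8, 25), planted_cpg_ids=(),
                      planted_set_name=None, seed=29)
    ds, control, truth = generate_dataset(cfg)
    return cfg, ds, control, truth
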