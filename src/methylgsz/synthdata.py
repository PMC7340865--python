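"""Synthetic 450K-style methylation data with known ground truth.

The generator emulates a whole-blood Illumina-450K experiment at desk
scale: a probes x samples beta matrix with island-relation-dependent
baseline methylation, per-sample covariate structure (age, sex, BMI,
six-part leukocyte composition, chip/array batch), a control-probe matrix
carrying the same chip offsets, planted per-CpG smoking effects, and an
optionally planted gene set whose member genes carry a milder but coherent
smoking shift. All effects are planted additively on the M scale, so a
planted shift equals the expected regression coefficient downstream.

Generative model (per probe i, sample j)::

    M_ij = base_i + a_i * (age_j - mean age) + x_i * sex_j
           + sum_c  c_ic * (prop_jc - mean prop_c)
           + l_i * u_chip(j)                       # batch component
           + smoking_j * delta_i                   # planted truth
           + Normal(0, noise_sd_m)

    beta_ij = 2^M / (1 + 2^M)

``base_i`` is the logit2 of an island-relation-dependent Beta draw (islands
hypomethylated, open sea hypermethylated), ``delta_i`` combines the
per-CpG plant and the planted-set plant, and the chip scores ``u`` are also
injected into the control-probe matrix so control-probe PCs can recover
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import (CELL_TYPES, GENE_REGION_GROUPS, ISLAND_RELATIONS,
                      DataError, MethylationDataset, ProbeAnnotation, SampleSheet)
from .genesets import GeneSetCollection

#: Mean leukocyte composition of adult whole blood (CD8T, CD4T, NK, B,
#: monocytes, granulocytes); granulocyte-dominant.
BLOOD_COMPOSITION = np.array([0.08, 0.15, 0.06, 0.07, 0.09, 0.55])

# Island-relation sampling weights for gene-annotated probes and the Beta
# parameters of the baseline methylation level per relation (islands are
# predominantly unmethylated, open sea predominantly methylated).
_RELATION_WEIGHTS = {"Island": 0.30, "N_Shore": 0.12, "S_Shore": 0.12,
                     "N_Shelf": 0.05, "S_Shelf": 0.05, "OpenSea": 0.36}
_BASELINE_BETA_PARAMS = {
    "Island": (2.0, 8.0),    # mean 0.2
    "N_Shore": (4.5, 5.5),   # mean 0.45
    "S_Shore": (4.5, 5.5),
    "N_Shelf": (7.0, 3.0),   # mean 0.7
    "S_Shelf": (7.0, 3.0),
    "OpenSea": (7.0, 3.0),
}
_REGION_GROUP_WEIGHTS = {"TSS200": 0.10, "TSS1500": 0.15, "5'UTR": 0.15,
                         "1stExon": 0.10, "Body": 0.40, "3'UTR": 0.10}


@dataclass
class SynthConfig:
    """Configuration of one synthetic dataset.

    The defaults mirror the study design the package targets: 125 samples
    of whom 21 are active smokers, a 20,000-probe slice of a 450K array,
    six-part blood composition, a chip batch structure, 20 planted smoking
    CpGs with a 1.0 M-unit shift and one planted gene set with a milder
    coherent 0.2 M-unit shift, and 16/125 samples missing alcohol/SES.
    """

    n_probes: int = 20_000
    n_samples: int = 125
    n_smokers: int = 21
    n_genes: int = 5_000
    probes_per_gene: float = 3.0      # Poisson mean, min 1 per gene
    frac_intergenic: float = 0.25
    n_sets: int = 150
    set_size_range: tuple = (10, 40)
    planted_cpg_ids: tuple | None = None  # default: 20 evenly spaced indices
    planted_cpg_delta_m: float = 1.0
    planted_set_name: str | None = "set_0001"
    planted_set_delta_m: float = 0.2
    planted_shore_delta_m: float = 0.0   # M-shift on all Shore probes (smokers)
    noise_sd_m: float = 0.5
    n_celltypes: int = 6
    n_chips: int = 6
    chip_effect_sd: float = 0.1
    n_control_probes: int = 200
    missing_covariate_rate: float = 16 / 125
    # covariate-effect magnitudes (per-probe coefficient spreads)
    age_effect_sd: float = 0.01       # M-units per year
    sex_effect_sd: float = 0.05
    cell_effect_sd: float = 0.5
    multi_gene_frac: float = 0.05     # genic probes annotated to a 2nd gene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_smokers >= self.n_samples:
            raise DataError("n_smokers must be < n_samples")
        if not 0 <= self.frac_intergenic <= 1:
            raise DataError("frac_intergenic must lie in [0,1]")
        lo, hi = self.set_size_range
        if lo < 2 or lo > hi:
            raise DataError("set_size_range must satisfy 2 <= min <= max")
        if self.planted_cpg_ids is None:
            step = max(1, self.n_probes // 20)
            self.planted_cpg_ids = tuple(range(0, self.n_probes, step))[:20]
        if any(not 0 <= i < self.n_probes for i in self.planted_cpg_ids):
            raise DataError("planted_cpg_ids must lie in [0, n_probes)")
        if self.n_celltypes != 6:
            raise DataError("the generator models the six-part blood composition")
        if self.noise_sd_m < 0 or self.chip_effect_sd < 0:
            raise DataError("noise/chip effect magnitudes must be non-negative")
        if not 0 <= self.missing_covariate_rate < 1:
            raise DataError("missing_covariate_rate must lie in [0,1)")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth of a generated dataset."""

    causal_probe_ids: list
    causal_set_names: list
    true_effect: pd.Series  # per-probe smoking effect, M-scale

    def write_tsv(self, path) -> None:
        out = self.true_effect.to_frame("true_effect_m")
        out["causal"] = out.index.isin(self.causal_probe_ids).astype(int)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    # independent stream per stage so annotation/genesets/dataset are each
    # reproducible whether called alone or from generate_dataset
    return np.random.default_rng([config.seed, stage])


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")


def _gene_name(i: int) -> str:
    return f"GENE{i + 1:05d}"


def generate_annotation(config: SynthConfig) -> ProbeAnnotation:
    """Manifest-style probe annotation with genes, region groups, islands.

    ``frac_intergenic`` of the probes get an empty gene field and OpenSea
    relation; the rest are distributed over ``n_genes`` genes with
    Poisson(probes_per_gene) probes each (min 1, totals repaired to match),
    and a small fraction carries a second gene annotation.
    """
    rng = _rng(config, 1)
    n = config.n_probes
    n_intergenic = int(round(config.frac_intergenic * n))
    n_genic = n - n_intergenic
    if n_genic > 0 and n_genic < config.n_genes:
        raise DataError("fewer gene-annotated probes than genes; lower n_genes "
                        "or frac_intergenic")

    probe_ids = _probe_ids(n)
    intergenic_mask = np.zeros(n, dtype=bool)
    intergenic_mask[rng.choice(n, size=n_intergenic, replace=False)] = True

    genes = [""] * n
    groups = [""] * n
    if n_genic:
        counts = 1 + rng.poisson(max(config.probes_per_gene - 1.0, 0.0), config.n_genes)
        # repair totals so that sum(counts) == n_genic, keeping every count >= 1
        diff = n_genic - int(counts.sum())
        while diff != 0:
            g = int(rng.integers(config.n_genes))
            if diff > 0:
                counts[g] += 1
                diff -= 1
            elif counts[g] > 1:
                counts[g] -= 1
                diff += 1
        assignment = np.repeat(np.arange(config.n_genes), counts)
        rng.shuffle(assignment)
        genic_positions = np.flatnonzero(~intergenic_mask)
        region_names = list(_REGION_GROUP_WEIGHTS)
        region_p = np.array(list(_REGION_GROUP_WEIGHTS.values()))
        for pos, g in zip(genic_positions, assignment):
            gene_list = [int(g)]
            if rng.random() < config.multi_gene_frac and config.n_genes > 1:
                other = int(rng.integers(config.n_genes - 1))
                gene_list.append(other + 1 if other >= g else other)
            grp = rng.choice(region_names, size=len(gene_list), p=region_p)
            genes[pos] = ";".join(_gene_name(x) for x in gene_list)
            groups[pos] = ";".join(grp)

    rel_names = list(_RELATION_WEIGHTS)
    rel_p = np.array(list(_RELATION_WEIGHTS.values()))
    relation = rng.choice(rel_names, size=n, p=rel_p)
    relation[intergenic_mask] = "OpenSea"

    table = pd.DataFrame({
        "chromosome": rng.integers(1, 23, size=n).astype(str),
        "position": rng.integers(1, 240_000_000, size=n),
        "gene_names": genes,
        "gene_region_groups": groups,
        "island_relation": relation,
    }, index=probe_ids)
    return ProbeAnnotation(table)


def generate_genesets(config: SynthConfig, annotation: ProbeAnnotation,
                      gmt_path=None) -> GeneSetCollection:
    """Sample ``n_sets`` gene sets from the annotated gene universe.

    Set sizes are uniform on ``set_size_range``; members are drawn without
    replacement within a set. Written as GMT when ``gmt_path`` is given.
    """
    rng = _rng(config, 2)
    universe = sorted({g for field_ in annotation.table["gene_names"]
                       for g in field_.split(";") if g})
    lo, hi = config.set_size_range
    if len(universe) < hi:
        raise DataError(f"gene universe ({len(universe)}) smaller than the "
                        f"maximum requested set size ({hi})")
    sets = {}
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"set_{i + 1:04d}"] = members
    coll = GeneSetCollection(sets, descriptions={k: "synthetic" for k in sets})
    if gmt_path is not None:
        coll.write_gmt(gmt_path)
    return coll


def generate_dataset(config: SynthConfig) -> tuple[MethylationDataset, pd.DataFrame, GroundTruth]:
    """Generate (dataset, control-probe matrix, ground truth).

    See the module docstring for the generative model. The planted per-CpG
    and planted-set effects are recorded in the returned ground truth; if
    ``planted_set_name`` does not exist among the generated sets an error
    is raised.
    """
    ann = generate_annotation(config)
    sets = generate_genesets(config, ann)
    rng = _rng(config, 3)
    n, ns = config.n_probes, config.n_samples

    # ---- sample sheet ----------------------------------------------------
    sample_ids = pd.Index([f"s{j + 1:03d}" for j in range(ns)], name="sample_id")
    smoking = np.zeros(ns, dtype=int)
    smoking[rng.choice(ns, size=config.n_smokers, replace=False)] = 1
    age = rng.uniform(40.0, 50.0, ns).round(1)
    sex = (rng.random(ns) < 0.38).astype(int)
    bmi = rng.normal(25.9, 4.4, ns).round(2)
    props = rng.dirichlet(BLOOD_COMPOSITION * 200.0, size=ns)
    chip = rng.integers(config.n_chips, size=ns)
    array_pos = rng.integers(12, size=ns)
    alcohol = np.round(rng.gamma(2.0, 3.0, ns), 1)
    ses = rng.choice(["manual", "lower_non_manual", "upper_non_manual"], size=ns)

    sheet = pd.DataFrame({
        "smoking": smoking, "age": age, "sex": sex, "bmi": bmi,
        **{ct: props[:, k] for k, ct in enumerate(CELL_TYPES)},
        "chip": [f"chip{c + 1}" for c in chip],
        "array_pos": [f"pos{p + 1:02d}" for p in array_pos],
        "alcohol": alcohol,
        "ses": ses,
    }, index=sample_ids)
    n_missing = int(round(config.missing_covariate_rate * ns))
    if n_missing:
        miss = rng.choice(ns, size=n_missing, replace=False)
        sheet.iloc[miss, sheet.columns.get_loc("alcohol")] = np.nan
        sheet.iloc[miss, sheet.columns.get_loc("ses")] = np.nan

    # ---- planted truth ---------------------------------------------------
    true_effect = np.zeros(n)
    true_effect[list(config.planted_cpg_ids)] += config.planted_cpg_delta_m
    causal_sets = []
    if config.planted_set_name is not None:
        if config.planted_set_name not in sets.sets:
            raise DataError(f"planted_set_name {config.planted_set_name!r} is not "
                            "among the generated sets")
        members = set(sets.sets[config.planted_set_name])
        in_set = ann.table["gene_names"].map(
            lambda f: any(g in members for g in f.split(";") if g))
        true_effect[in_set.to_numpy()] += config.planted_set_delta_m
        causal_sets.append(config.planted_set_name)
    if config.planted_shore_delta_m != 0.0:
        shore = ann.table["island_relation"].isin(["N_Shore", "S_Shore"])
        true_effect[shore.to_numpy()] += config.planted_shore_delta_m

    # ---- signal assembly (M scale) --------------------------------------
    rel = ann.table["island_relation"].to_numpy()
    base_beta = np.empty(n)
    for relation, (a, b) in _BASELINE_BETA_PARAMS.items():
        mask = rel == relation
        base_beta[mask] = rng.beta(a, b, size=int(mask.sum()))
    base_beta = np.clip(base_beta, 0.02, 0.98)
    base_m = np.log2(base_beta / (1.0 - base_beta))

    age_slope = rng.normal(0.0, config.age_effect_sd, n)
    sex_off = rng.normal(0.0, config.sex_effect_sd, n)
    cell_sig = rng.normal(0.0, config.cell_effect_sd, (n, 6))
    chip_u = rng.normal(0.0, config.chip_effect_sd, config.n_chips)
    chip_load = rng.normal(1.0, 0.3, n)

    centered_age = age - age.mean()
    centered_props = props - BLOOD_COMPOSITION

    M = (base_m[:, None]
         + np.outer(age_slope, centered_age)
         + np.outer(sex_off, sex)
         + cell_sig @ centered_props.T
         + np.outer(chip_load, chip_u[chip])
         + np.outer(true_effect, smoking))
    if config.noise_sd_m > 0:
        M += rng.normal(0.0, config.noise_sd_m, (n, ns))
    M = np.clip(M, -19.0, 19.0)
    beta = 1.0 / (1.0 + np.exp2(-M))

    ds = MethylationDataset(
        pd.DataFrame(beta, index=ann.probe_ids, columns=sample_ids),
        ann, SampleSheet(sheet),
    )

    # ---- control probes (same chip scores, own loadings) -----------------
    ctrl_base = rng.normal(10.0, 1.0, config.n_control_probes)
    ctrl_load = rng.normal(1.0, 0.3, config.n_control_probes)
    ctrl = (ctrl_base[:, None]
            + np.outer(ctrl_load, chip_u[chip])
            + rng.normal(0.0, 0.05, (config.n_control_probes, ns)))
    control = pd.DataFrame(
        ctrl, index=[f"ctrl{i + 1:04d}" for i in range(config.n_control_probes)],
        columns=sample_ids,
    )

    truth = GroundTruth(
        causal_probe_ids=list(ann.probe_ids[np.flatnonzero(true_effect != 0)]),
        causal_set_names=causal_sets,
        true_effect=pd.Series(true_effect, index=ann.probe_ids, name="true_effect_m"),
    )
    return ds, control, truth


def write_all(config: SynthConfig, outdir) -> dict:
    """Generate everything and write the plain-text files; returns the paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds, control, truth = generate_dataset(config)
    sets = generate_genesets(config, ds.annotation)
    paths = {
        "beta": out / "beta.tsv",
        "sample_sheet": out / "sample_sheet.csv",
        "annotation": out / "annotation.tsv",
        "control": out / "control_probes.tsv",
        "gmt": out / "gene_sets.gmt",
        "ground_truth": out / "ground_truth.tsv",
    }
    ds.write(paths["beta"], paths["annotation"], paths["sample_sheet"])
    control.to_csv(paths["control"], sep="\t")
    sets.write_gmt(paths["gmt"])
    truth.write_tsv(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
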