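"""Synthetic cohorts with known ground truth.

Generates the three data layers the analysis consumes — a subtyped
gene-expression matrix, a marker-level copy-number cohort with planted
recurrent gain/loss events, and a clinical table with subtype-dependent
covariates and survival — so that every downstream stage can be tested
against a known answer.

The expression model is deliberately the minimal structure consensus
clustering assumes: gene-wise independent Gaussians where each informative
gene carries a mean shift in exactly one subtype.  Copy-number profiles are
sums of carried event amplitudes plus Gaussian marker noise on an equally
spaced multi-chromosome genome.  Survival is exponential per subtype with
independent uniform censoring.

One shared seed expands into fixed per-component child seeds, so adding a
generator call never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .copy_number import CopyNumberCohort
from .errors import ConfigError, DataError

__all__ = [
    "Chromosome",
    "CNEvent",
    "SimConfig",
    "simulate_subtyped_expression",
    "informative_gene_map",
    "simulate_copy_number_cohort",
    "simulate_clinical_outcomes",
    "write_simulated_cohort",
]

# fixed spawn keys: adding a component must not perturb earlier draws
_EXPR_KEY, _CN_KEY, _CLIN_KEY = 11, 13, 17


@dataclass(frozen=True)
class Chromosome:
    name: str
    arm_boundary: int  # bp position where the q arm starts
    n_markers: int
    length: int  # bp


@dataclass(frozen=True)
class CNEvent:
    direction: str  # "gain" | "loss"
    chrom: str
    start: int  # bp
    end: int
    amplitude: float  # log2 units, >0 for gains, <0 for losses
    carrier_fraction: float
    subtypes: tuple = None  # affected subtype indices; None = all


def _default_genome() -> tuple:
    # reduced multi-chromosome genome: 8 chromosomes, 250 markers each
    return tuple(
        Chromosome(name=f"chr{i + 1}", arm_boundary=60_000_000,
                   n_markers=250, length=150_000_000)
        for i in range(8)
    )


def _default_cn_events() -> tuple:
    # one broad gain and one broad loss, each enriched in specific subtypes,
    # echoing the arm-level gains/losses recurrent in squamous tumors
    return (
        CNEvent("gain", "chr2", 70_000_000, 100_000_000, 0.6, 0.4, (0, 3)),
        CNEvent("loss", "chr5", 10_000_000, 40_000_000, -0.6, 0.4, (0, 3)),
    )


def _default_clinical_effects() -> dict:
    # per-covariate subtype-conditional category probabilities (K=4)
    return {
        "site": {
            "categories": ["larynx", "oral_cavity", "oropharynx", "hypopharynx"],
            "probs": [[0.23, 0.68, 0.07, 0.02],
                      [0.12, 0.55, 0.15, 0.18],
                      [0.16, 0.06, 0.63, 0.15],
                      [0.38, 0.17, 0.21, 0.24]],
        },
        "node_status": {
            "categories": ["N0-N1", "N2-N3"],
            "probs": [[0.71, 0.29], [0.54, 0.46], [0.25, 0.75], [0.64, 0.36]],
        },
        "treatment": {
            "categories": ["chemo_rt", "surgery"],
            "probs": [[0.25, 0.75], [0.39, 0.61], [0.84, 0.16], [0.43, 0.57]],
        },
        "hpv_status": {
            "categories": ["negative", "positive"],
            "probs": [[0.96, 0.04], [0.88, 0.12], [0.68, 0.32], [0.89, 0.11]],
        },
    }


def _default_survival() -> dict:
    # events/month per subtype; modest differences with moderate censoring
    return {"hazards": (0.02, 0.02, 0.035, 0.02), "censoring_rate": 0.3}


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic study cohort.

    Defaults emulate the scale of a ~138-sample, ~15597-gene tumor study
    with 4 expression subtypes: informative genes carry an ``effect_size``
    log2 mean shift in exactly one subtype over ``noise_sd`` Gaussian noise.
    """

    n_samples: int = 138
    n_genes: int = 15597
    n_subtypes: int = 4
    n_informative_genes_per_subtype: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    genome: tuple = field(default_factory=_default_genome)
    cn_events: tuple = field(default_factory=_default_cn_events)
    cn_noise_sd: float = 0.2
    clinical_effects: dict = field(default_factory=_default_clinical_effects)
    survival: dict = field(default_factory=_default_survival)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise ConfigError("need at least 2 subtypes")
        for name in ("n_samples", "n_genes", "n_subtypes",
                     "n_informative_genes_per_subtype"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_informative_genes_per_subtype * self.n_subtypes > self.n_genes:
            raise ConfigError("informative genes exceed total genes")
        if self.noise_sd < 0 or self.cn_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        chrom_names = {c.name for c in self.genome}
        for ev in self.cn_events:
            if not 0 <= ev.carrier_fraction <= 1:
                raise ConfigError("carrier_fraction must lie in [0, 1]")
            if ev.direction == "gain" and ev.amplitude <= 0:
                raise ConfigError("gain amplitude must be > 0")
            if ev.direction == "loss" and ev.amplitude >= 0:
                raise ConfigError("loss amplitude must be < 0")
            if ev.chrom not in chrom_names:
                raise ConfigError(f"event chromosome {ev.chrom!r} not in genome")
        for cov, dist in self.clinical_effects.items():
            probs = np.asarray(dist["probs"], dtype=float)
            if probs.shape != (self.n_subtypes, len(dist["categories"])):
                raise ConfigError(f"covariate {cov!r}: probability table shape mismatch")
            if not np.allclose(probs.sum(axis=1), 1.0):
                raise ConfigError(f"covariate {cov!r}: probabilities must sum to 1")
        hazards = self.survival.get("hazards")
        if hazards is None or len(hazards) < self.n_subtypes:
            raise ConfigError("survival hazards missing for some subtype")

    def rng(self, component_key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(component_key,)))


def informative_gene_map(config: SimConfig) -> dict:
    """Ground-truth marker genes: subtype index -> list of gene ids."""
    m = config.n_informative_genes_per_subtype
    return {k: [f"S{k + 1}marker{i:04d}" for i in range(m)]
            for k in range(config.n_subtypes)}


def _gene_ids(config: SimConfig) -> list:
    ids = []
    gmap = informative_gene_map(config)
    for k in range(config.n_subtypes):
        ids.extend(gmap[k])
    ids.extend(f"G{i:05d}" for i in range(config.n_genes - len(ids)))
    return ids


def simulate_subtyped_expression(config: SimConfig):
    """Draw a gene x sample log2 expression matrix with planted subtypes.

    Returns ``(matrix, labels)`` where labels (0..K-1) are balanced up to
    rounding and randomly ordered across samples.  Informative genes carry a
    ``+effect_size`` shift in their subtype; all other genes are pure noise.
    """
    rng = config.rng(_EXPR_KEY)
    n, g, k = config.n_samples, config.n_genes, config.n_subtypes
    base = np.tile(np.arange(k), n // k + 1)[:n]
    labels = base[rng.permutation(n)]
    values = rng.normal(0.0, config.noise_sd, size=(g, n))
    m = config.n_informative_genes_per_subtype
    for c in range(k):
        rows = slice(c * m, (c + 1) * m)
        values[rows, labels == c] += config.effect_size
    sample_ids = [f"T{i + 1:04d}" for i in range(n)]
    matrix = pd.DataFrame(values, index=_gene_ids(config), columns=sample_ids)
    return matrix, pd.Series(labels, index=sample_ids, name="subtype")


def _marker_table(config: SimConfig):
    rows = []
    for chrom in config.genome:
        step = chrom.length / chrom.n_markers
        for i in range(chrom.n_markers):
            pos = int(step * (i + 0.5))
            rows.append((chrom.name, pos))
    markers = pd.DataFrame(rows, columns=["chrom", "pos"])
    markers.index = [f"m{i + 1:05d}" for i in range(len(markers))]
    boundaries = {c.name: c.arm_boundary for c in config.genome}
    arm = [f"{c}p" if p < boundaries[c] else f"{c}q"
           for c, p in zip(markers["chrom"], markers["pos"])]
    return markers, pd.Series(arm, index=markers.index)


def simulate_copy_number_cohort(config: SimConfig, labels: pd.Series):
    """Build marker-level CN profiles with planted recurrent events.

    Each sample's profile is the sum of its carried event amplitudes over
    the markers the event covers, plus N(0, cn_noise_sd) marker noise.
    Carriers are drawn per event at ``carrier_fraction`` within the affected
    subtypes.  Returns ``(cohort, ground_truth)`` where the ground truth
    lists carriers and covered markers per event.
    """
    if len(labels) != config.n_samples:
        raise ConfigError("labels length must equal n_samples")
    rng = config.rng(_CN_KEY)
    markers, arm_map = _marker_table(config)
    n = config.n_samples
    values = rng.normal(0.0, config.cn_noise_sd, size=(len(markers), n))
    lengths = {c.name: c.length for c in config.genome}
    truth = []
    lab = labels.to_numpy()
    for ev in config.cn_events:
        if not (0 <= ev.start < ev.end <= lengths[ev.chrom]):
            raise ConfigError(
                f"event on {ev.chrom} [{ev.start}, {ev.end}) outside chromosome")
        covered = ((markers["chrom"] == ev.chrom) & (markers["pos"] >= ev.start)
                   & (markers["pos"] < ev.end)).to_numpy()
        affected = (np.ones(n, dtype=bool) if ev.subtypes is None
                    else np.isin(lab, np.asarray(ev.subtypes)))
        carrier = affected & (rng.random(n) < ev.carrier_fraction)
        values[np.ix_(covered, carrier)] += ev.amplitude
        truth.append({
            "direction": ev.direction, "chrom": ev.chrom,
            "start": ev.start, "end": ev.end, "amplitude": ev.amplitude,
            "carriers": list(np.asarray(labels.index)[carrier]),
            "markers": list(markers.index[covered]),
        })
    cohort = CopyNumberCohort(
        markers=markers,
        values=pd.DataFrame(values, index=markers.index, columns=labels.index),
        arm_map=arm_map)
    return cohort, truth


def simulate_clinical_outcomes(config: SimConfig, labels: pd.Series) -> pd.DataFrame:
    """Draw subtype-conditional clinical covariates and survival outcomes.

    Survival times are exponential with the per-subtype hazard; a sample is
    censored independently with probability ``censoring_rate``, in which
    case the observed time is uniform on (0, event time) and the event flag
    is 0 (1 = death/recurrence).
    """
    if len(labels) != config.n_samples:
        raise ConfigError("labels length must equal n_samples")
    rng = config.rng(_CLIN_KEY)
    lab = labels.to_numpy()
    hazards = np.asarray(config.survival["hazards"], dtype=float)
    if len(hazards) < config.n_subtypes:
        raise ConfigError("survival hazards missing for some subtype")
    if np.any(hazards[:config.n_subtypes] <= 0):
        raise ConfigError("hazards must be positive for every subtype")
    cens_rate = float(config.survival.get("censoring_rate", 0.0))
    out = pd.DataFrame(index=labels.index)
    out["subtype"] = lab
    for cov, dist in config.clinical_effects.items():
        cats = dist["categories"]
        probs = np.asarray(dist["probs"], dtype=float)
        draws = np.array([rng.choice(len(cats), p=probs[s]) for s in lab])
        out[cov] = [cats[d] for d in draws]
    event_time = rng.exponential(1.0 / hazards[lab])
    censored = rng.random(len(lab)) < cens_rate
    observed = np.where(censored, rng.uniform(0, event_time), event_time)
    out["rfs_months"] = observed
    out["event"] = (~censored).astype(int)
    return out


def write_simulated_cohort(outdir, config: SimConfig) -> dict:
    """Generate all three layers and write them as TSV/JSON under outdir."""
    from pathlib import Path
    from .copy_number import write_marker_matrix
    from .expression_prep import write_expression_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, labels = simulate_subtyped_expression(config)
    cohort, truth = simulate_copy_number_cohort(config, labels)
    clinical = simulate_clinical_outcomes(config, labels)
    write_expression_matrix(matrix, outdir / "expression.tsv")
    labels.rename("subtype").to_csv(outdir / "labels.tsv", sep="\t",
                                    index_label="sample_id")
    write_marker_matrix(cohort, outdir / "copy_number.tsv")
    with open(outdir / "cn_ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index_label="sample_id")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    return {"expression": str(outdir / "expression.tsv"),
            "labels": str(outdir / "labels.tsv"),
            "copy_number": str(outdir / "copy_number.tsv"),
            "clinical": str(outdir / "clinical.tsv")}
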