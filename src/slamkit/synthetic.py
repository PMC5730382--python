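"""Seeded generators for every input the analysis consumes.

Each generator is a pure function of its parameters and a seed, and emits
objects that satisfy the invariants of the consuming module. Defaults encode
the study conditions the analyses assume:

* ``gen_counts`` — two RNA-immunoprecipitation experiments with
  negative-binomial counts, 102 and 16 planted enriched transcripts sharing 3
  (the bait among them, planted with the strongest effect), 4 replicate
  pairs, library depth 10^6.
* ``gen_decay_trace`` — a cycloheximide-chase fluorescence decay: half-life
  40 min sampled at 11 points over 10 min with 2% Gaussian noise.
* ``gen_recovery_trace`` — a linear post-bleach recovery trace.
* ``gen_cds`` — a coding sequence with codons drawn by usage frequency, no
  internal stops, terminated by a stop codon.
* ``gen_cq`` — target/reference qPCR Cq tables in technical duplicate with a
  planted expression ratio.
* ``gen_furrow_measurements`` — per-embryo, per-furrow intensities with a
  step-up at a stage time (3 embryos × 10 furrows, 6-fold step).

Noise models are Gaussian on the intensity and Cq scales; counts are
negative-binomial with configurable dispersion (Poisson at dispersion 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import CdsSequence, CodonUsageTable, STOP, load_dmel_usage
from .kinetics import FluorescenceTrace
from .rip import CountMatrix

__all__ = [
    "SimConfig",
    "CountTruth",
    "gen_counts",
    "gen_decay_trace",
    "gen_recovery_trace",
    "gen_cds",
    "gen_cq",
    "gen_furrow_measurements",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the two-experiment RIP count simulation."""

    seed: int = 0
    n_transcripts: int = 2000
    n_enriched_a: int = 102  # antibody-pulldown design
    n_enriched_b: int = 16  # GFP-binder design
    n_shared: int = 3
    effect_fold: float = 8.0
    bait_fold: float = 20.0  # the bait transcript carries the strongest enrichment
    library_depth: float = 1e6
    dispersion: float = 0.01  # NB dispersion phi: var = m + phi*m^2
    n_replicates: int = 4  # replicate pairs per experiment (study used 2-4)
    weight_low: float = 5.0  # baseline-abundance weights, log-uniform range
    weight_high: float = 50.0

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_enriched_a, self.n_enriched_b):
            raise ValueError("n_shared must not exceed either enriched set")
        if self.n_enriched_a + self.n_enriched_b - self.n_shared > self.n_transcripts:
            raise ValueError("planted sets exceed the transcript pool")
        if not self.effect_fold > 1:
            raise ValueError("effect_fold must exceed 1")
        if self.dispersion < 0 or self.library_depth <= 0 or self.n_replicates < 1:
            raise ValueError("invalid simulation parameters")


@dataclass(frozen=True)
class CountTruth:
    """Planted ground truth for a two-experiment count simulation."""

    enriched_a: frozenset[str]
    enriched_b: frozenset[str]
    bait: str

    @property
    def shared(self) -> frozenset[str]:
        return self.enriched_a & self.enriched_b


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _one_experiment(
    rng: np.random.Generator,
    ids: list[str],
    enriched: set[str],
    cfg: SimConfig,
) -> CountMatrix:
    n = len(ids)
    weights = np.exp(rng.uniform(np.log(cfg.weight_low), np.log(cfg.weight_high), n))
    effect = np.ones(n)
    for i, t in enumerate(ids):
        if t in enriched:
            effect[i] = cfg.bait_fold if t == "slam" else cfg.effect_fold
    ctrl_mean = cfg.library_depth * weights / weights.sum()
    ip_w = weights * effect
    ip_mean = cfg.library_depth * ip_w / ip_w.sum()
    data = {}
    for rep in range(1, cfg.n_replicates + 1):
        data[f"IP_{rep}"] = _nb_draw(rng, ip_mean, cfg.dispersion)
        data[f"control_{rep}"] = _nb_draw(rng, ctrl_mean, cfg.dispersion)
    counts = pd.DataFrame(data, index=pd.Index(ids, name="transcript_id"))
    return CountMatrix.from_frame(counts)


def gen_counts(cfg: SimConfig = SimConfig()) -> tuple[CountMatrix, CountMatrix, CountTruth]:
    """Two IP/control count matrices with planted enriched transcripts.

    The planted IP/control mean ratio equals ``effect_fold`` before
    normalization (``bait_fold`` for the bait transcript ``slam``, which is
    always in the shared set). Identical config (including seed) reproduces
    identical matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = ["slam"] + [f"tr{i:04d}" for i in range(1, cfg.n_transcripts)]
    # deterministic planted identity: bait first, then disjoint exclusive sets
    shared = ids[: cfg.n_shared]
    only_a = ids[cfg.n_shared : cfg.n_shared + cfg.n_enriched_a - cfg.n_shared]
    start_b = cfg.n_shared + len(only_a)
    only_b = ids[start_b : start_b + cfg.n_enriched_b - cfg.n_shared]
    enriched_a, enriched_b = set(shared) | set(only_a), set(shared) | set(only_b)
    matrix_a = _one_experiment(rng, ids, enriched_a, cfg)
    matrix_b = _one_experiment(rng, ids, enriched_b, cfg)
    truth = CountTruth(
        enriched_a=frozenset(enriched_a), enriched_b=frozenset(enriched_b), bait="slam"
    )
    return matrix_a, matrix_b, truth


def gen_decay_trace(
    t_half: float = 40.0,
    noise_sd: float = 2.0,
    n_points: int = 11,
    dt: float = 1.0,
    seed: int = 0,
    I0: float = 100.0,
) -> FluorescenceTrace:
    """Exponential-decay trace I(t) = I0·2^(−t/t_half) + Gaussian noise."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    intensities = I0 * np.power(2.0, -t / t_half) + rng.normal(0.0, noise_sd, n_points)
    return FluorescenceTrace(times=t, intensities=np.clip(intensities, 0.0, None))


def gen_recovery_trace(
    slope: float = 2.0,
    intercept: float = 10.0,
    noise_sd: float = 1.0,
    n_points: int = 21,
    dt: float = 0.5,
    seed: int = 0,
) -> FluorescenceTrace:
    """Linear post-bleach recovery trace with Gaussian noise."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    intensities = intercept + slope * t + rng.normal(0.0, noise_sd, n_points)
    return FluorescenceTrace(times=t, intensities=np.clip(intensities, 0.0, None))


def gen_cds(
    n_codons: int,
    usage: CodonUsageTable | None = None,
    seed: int = 0,
    id: str = "synthetic_cds",
) -> CdsSequence:
    """Random CDS: ATG start, usage-weighted sense codons, one trailing stop.

    ``n_codons`` counts the sense codons (the trailing stop adds one more), so
    the sequence length is 3·(n_codons + 1).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    usage = usage if usage is not None else load_dmel_usage()
    rng = np.random.default_rng(seed)
    code = usage.code
    amino_acids = sorted(set(code.mapping.values()) - {STOP})
    codons = ["ATG"]
    for _ in range(n_codons - 1):
        aa = amino_acids[rng.integers(len(amino_acids))]
        fam = code.family(aa)
        w = np.array([usage[c] for c in fam])
        codons.append(fam[rng.choice(len(fam), p=w / w.sum())])
    stops = code.family(STOP)
    w = np.array([usage[c] for c in stops])
    codons.append(stops[rng.choice(len(stops), p=w / w.sum())])
    return CdsSequence(id=id, seq="".join(codons))


def gen_cq(
    true_ratio: float = 10.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.2,
    n_rep: int = 3,
    seed: int = 0,
    target: str = "target",
    reference: str = "reference",
    reference_cq: float = 20.0,
    include_no_rt: bool = True,
) -> pd.DataFrame:
    """Cq table with a planted target/reference ratio, reactions in duplicate.

    ΔCq is planted as −log_E(true_ratio); each reaction contributes two
    technical-duplicate rows with Gaussian Cq noise. ``n_rep`` biological
    samples are generated; no-RT control rows sit 15 cycles above template.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    rng = np.random.default_rng(seed)
    delta_cq = -math.log(true_ratio) / math.log(efficiency)
    rows = []
    for s in range(1, n_rep + 1):
        sample = f"s{s}"
        for name, base in ((reference, reference_cq), (target, reference_cq + delta_cq)):
            for _ in range(2):  # technical duplicates
                rows.append(
                    {
                        "target": name,
                        "sample": sample,
                        "cq": base + rng.normal(0.0, noise_sd),
                        "is_no_rt": False,
                    }
                )
        if include_no_rt:
            for name in (reference, target):
                rows.append(
                    {
                        "target": name,
                        "sample": sample,
                        "cq": reference_cq + 15.0,
                        "is_no_rt": True,
                    }
                )
    return pd.DataFrame(rows)


def gen_furrow_measurements(
    step_time: float = 0.0,
    low_mean: float = 10.0,
    high_mean: float = 60.0,
    n_embryos: int = 3,
    n_furrows: int = 10,
    noise_sd: float = 2.0,
    seed: int = 0,
    stage_times: tuple[float, ...] = (-10.0, -5.0, 5.0, 10.0, 20.0, 30.0),
    channels: tuple[str, ...] = ("RNA", "protein"),
    embryo_sd: float = 0.05,
) -> pd.DataFrame:
    """Per-furrow intensities stepping from low to high at ``step_time``.

    Stage times are minutes relative to mitosis 13; each embryo carries a
    multiplicative random effect (sd ``embryo_sd``) on top of per-furrow
    Gaussian noise. Defaults mirror 3 embryos with ~10 furrows scored each.
    """
    if not high_mean >= low_mean >= 0:
        raise ValueError("require high_mean >= low_mean >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(1, n_embryos + 1):
        embryo_factor = rng.normal(1.0, embryo_sd)
        for stage in stage_times:
            base = low_mean if stage < step_time else high_mean
            for ch in channels:
                for f in range(1, n_furrows + 1):
                    intensity = base * embryo_factor + rng.normal(0.0, noise_sd)
                    rows.append(
                        {
                            "embryo": f"e{e}",
                            "stage_min": stage,
                            "furrow": f,
                            "channel": ch,
                            "intensity": max(intensity, 0.0),
                        }
                    )
    return pd.DataFrame(rows)
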