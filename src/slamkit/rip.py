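"""RNA-immunoprecipitation enrichment calling.

Transcripts specifically associated with a bait protein are called from
IP-versus-control count matrices: weakly expressed transcripts are removed by
a raw-count filter, a per-transcript enrichment factor is computed as the
(normalized, pseudocounted) IP/control ratio combined across replicate pairs,
and transcripts whose factor strictly exceeds a fold-change threshold are
called. Two independent pulldown designs are then intersected; the shared set
is the high-confidence bound fraction.

Interpretation choices that the upstream experimental description leaves open
are explicit config fields: the filter statistic is the maximum raw count
across all samples of a transcript; normalization defaults to counts per
million per sample; replicates combine by geometric mean of per-pair ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "EnrichmentConfig",
    "VennSummary",
    "filter_low_counts",
    "enrichment_factor",
    "call_enriched",
    "intersect_experiments",
    "rank_transcripts",
]

ROLE_IP = "IP"
ROLE_CONTROL = "control"


@dataclass
class CountMatrix:
    """Transcripts × samples nonnegative integer counts with sample roles.

    ``counts`` is indexed by transcript id; columns are sample names. ``roles``
    and ``replicates`` map sample name → role ('IP'/'control') and replicate id.
    Replicate ids pair IP and control samples for ratio computation.
    """

    counts: pd.DataFrame
    roles: dict[str, str]
    replicates: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate transcript ids: {list(dupes[:5])}")
        if set(self.counts.columns) != set(self.roles):
            raise ValueError("roles must cover exactly the sample columns")
        if set(self.counts.columns) != set(self.replicates):
            raise ValueError("replicates must cover exactly the sample columns")
        bad_roles = set(self.roles.values()) - {ROLE_IP, ROLE_CONTROL}
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        if ROLE_IP not in self.roles.values() or ROLE_CONTROL not in self.roles.values():
            raise ValueError("need at least one IP and one control sample")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    def samples(self, role: str) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == role]

    def replicate_pairs(self) -> list[tuple[str, str, str]]:
        """(replicate id, IP sample, control sample) for each paired replicate."""
        ip = {self.replicates[s]: s for s in self.samples(ROLE_IP)}
        ctrl = {self.replicates[s]: s for s in self.samples(ROLE_CONTROL)}
        shared = sorted(set(ip) & set(ctrl))
        if not shared:
            raise ValueError("no replicate id is present in both IP and control samples")
        return [(r, ip[r], ctrl[r]) for r in shared]

    @classmethod
    def from_frame(cls, counts: pd.DataFrame) -> "CountMatrix":
        """Build from a frame whose columns are named ``<role>_<replicate>``."""
        roles, reps = {}, {}
        for col in counts.columns:
            role, _, rep = str(col).partition("_")
            if role not in (ROLE_IP, ROLE_CONTROL) or not rep:
                raise ValueError(
                    f"sample column {col!r} must be named '<role>_<replicate>' "
                    f"with role in {{IP, control}}"
                )
            roles[col], reps[col] = role, rep
        return cls(counts=counts, roles=roles, replicates=reps)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds and combination rules for enrichment calling.

    min_count is 50 for the antibody-pulldown design and 10 for the
    GFP-binder design; the 4-fold threshold is strict (factor must exceed it).
    """

    threshold: float = 4.0
    min_count: int = 50
    pseudocount: float = 1.0
    normalization: str = "counts-per-million"  # or "none"
    replicate_combine: str = "geometric-mean"  # or "mean-of-ratios"

    def __post_init__(self) -> None:
        if not self.threshold > 1:
            raise ValueError("threshold must exceed 1")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.normalization not in ("counts-per-million", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.replicate_combine not in ("geometric-mean", "mean-of-ratios"):
            raise ValueError(f"unknown replicate_combine {self.replicate_combine!r}")


def filter_low_counts(m: CountMatrix, min_count: int) -> CountMatrix:
    """Drop transcripts whose maximum raw count across samples is < min_count."""
    keep = m.counts.max(axis=1) >= min_count
    return CountMatrix(
        counts=m.counts.loc[keep], roles=dict(m.roles), replicates=dict(m.replicates)
    )


def _normalized(m: CountMatrix, cfg: EnrichmentConfig) -> pd.DataFrame:
    if cfg.normalization == "none":
        return m.counts.astype(float)
    sums = m.counts.sum(axis=0).astype(float)
    if (sums == 0).any():
        zero = list(sums.index[sums == 0])
        raise ValueError(f"cannot CPM-normalize all-zero sample columns: {zero}")
    return m.counts / sums * 1e6


def enrichment_factor(m: CountMatrix, cfg: EnrichmentConfig = EnrichmentConfig()) -> pd.DataFrame:
    """Per-transcript enrichment factors.

    Returns a frame indexed by transcript with one ``ratio_<rep>`` column per
    replicate pair, the combined ``factor``, and a strict-threshold ``passed``
    flag. With pseudocount 0 a zero control value raises, pointing at the
    pseudocount, rather than emitting infinities.
    """
    norm = _normalized(m, cfg)
    pairs = m.replicate_pairs()
    out = pd.DataFrame(index=m.counts.index)
    ratios = []
    for rep, ip, ctrl in pairs:
        denom = norm[ctrl] + cfg.pseudocount
        if (denom == 0).any():
            raise ZeroDivisionError(
                "control value of 0 with pseudocount 0; set a positive pseudocount"
            )
        r = (norm[ip] + cfg.pseudocount) / denom
        out[f"ratio_{rep}"] = r
        ratios.append(r)
    stacked = np.column_stack([r.to_numpy() for r in ratios])
    if cfg.replicate_combine == "geometric-mean":
        factor = np.exp(np.mean(np.log(np.maximum(stacked, 1e-300)), axis=1))
        factor[np.any(stacked == 0, axis=1)] = 0.0
    else:
        factor = stacked.mean(axis=1)
    out["factor"] = factor
    out["passed"] = out["factor"] > cfg.threshold
    return out


def call_enriched(table: pd.DataFrame, threshold: float = 4.0) -> set[str]:
    """Transcripts whose factor strictly exceeds the threshold."""
    return set(table.index[table["factor"] > threshold])


@dataclass(frozen=True)
class VennSummary:
    """Two-set Venn: shared transcripts plus exclusive counts."""

    shared: frozenset[str]
    n_only_a: int
    n_only_b: int

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    def as_dict(self) -> dict:
        return {
            "n_only_a": self.n_only_a,
            "n_shared": self.n_shared,
            "n_only_b": self.n_only_b,
            "shared": sorted(self.shared),
        }


def intersect_experiments(a: Iterable[str], b: Iterable[str]) -> VennSummary:
    """Intersect called sets from two pulldown designs."""
    sa, sb = set(a), set(b)
    return VennSummary(
        shared=frozenset(sa & sb), n_only_a=len(sa - sb), n_only_b=len(sb - sa)
    )


def rank_transcripts(table: pd.DataFrame) -> list[str]:
    """Transcript ids by descending factor; ties broken by id."""
    order = sorted(table.index, key=lambda t: (-table.at[t, "factor"], t))
    return order
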