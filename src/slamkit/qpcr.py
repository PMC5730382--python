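"""Relative RNA quantification from qPCR quantification cycles (Cq).

Technical replicates (reactions run in duplicate) are averaged on the Cq
scale, the cycle difference ΔCq = Cq(target) − Cq(reference) is converted to
an expression ratio E^(−ΔCq) under an assumed amplification efficiency E
(default 2.0, i.e. perfect doubling per cycle), and no-reverse-transcriptase
controls are checked against the template reactions.

No ΔΔCq reference-gene step is applied: the target is normalized directly to
a second target measured in the same sample (e.g. a recoded allele against
the wild-type allele in the same embryos).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "MeanCq",
    "RelativeExpression",
    "mean_cq",
    "relative_expression",
    "no_rt_check",
    "validate_cq_table",
    "expression_ratio_from_table",
]

CQ_COLUMNS = ("target", "sample", "cq", "is_no_rt")


@dataclass(frozen=True)
class MeanCq:
    value: float  # cycles
    spread: float  # max - min over replicates, cycles
    flagged: bool  # spread exceeded the tolerance


def mean_cq(replicates: Sequence[float], tolerance: float = 0.5) -> MeanCq:
    """Arithmetic mean on the Cq scale; spreads beyond ``tolerance`` are flagged."""
    vals = [float(v) for v in replicates]
    if not vals:
        raise ValueError("need at least one Cq value")
    spread = max(vals) - min(vals)
    flagged = spread > tolerance
    if flagged:
        warnings.warn(
            f"replicate Cq spread {spread:.2f} exceeds tolerance {tolerance}",
            stacklevel=2,
        )
    return MeanCq(value=sum(vals) / len(vals), spread=spread, flagged=flagged)


@dataclass(frozen=True)
class RelativeExpression:
    """Expression ratio target/reference with its ΔCq and assumed efficiency."""

    delta_cq: float  # cycles
    ratio: float
    log2_ratio: float
    efficiency: float


def relative_expression(
    target_cq: float, reference_cq: float, efficiency: float = 2.0
) -> RelativeExpression:
    """ratio = E^(−ΔCq) with ΔCq = Cq(target) − Cq(reference); E in (1, 2]."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")
    delta = float(target_cq) - float(reference_cq)
    ratio = efficiency ** (-delta)
    return RelativeExpression(
        delta_cq=delta,
        ratio=ratio,
        log2_ratio=math.log2(ratio),
        efficiency=efficiency,
    )


def validate_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and Cq range (0, 50); NaN Cq allowed only for no-RT rows."""
    missing = set(CQ_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Cq table missing columns {sorted(missing)}")
    tmpl = table[~table["is_no_rt"].astype(bool)]
    cq = tmpl["cq"].astype(float)
    if cq.isna().any() or ((cq <= 0) | (cq >= 50)).any():
        raise ValueError("template Cq values must be in (0, 50)")
    return table


def no_rt_check(table: pd.DataFrame, margin: float = 5.0) -> dict[str, bool]:
    """Per target: no-RT control Cq must trail the template Cq by >= margin.

    An undetermined no-RT Cq (NaN — no amplification at all) passes. Targets
    without a no-RT row are skipped with a warning.
    """
    validate_cq_table(table)
    results: dict[str, bool] = {}
    for target, grp in table.groupby("target"):
        no_rt = grp[grp["is_no_rt"].astype(bool)]
        templ = grp[~grp["is_no_rt"].astype(bool)]
        if no_rt.empty:
            warnings.warn(f"target {target!r} has no no-RT control row; skipped", stacklevel=2)
            continue
        if templ.empty:
            raise ValueError(f"target {target!r} has only no-RT rows")
        template_cq = templ["cq"].astype(float).mean()
        flags = []
        for v in no_rt["cq"]:
            v = float(v)
            flags.append(math.isnan(v) or v - template_cq >= margin)
        results[str(target)] = all(flags)
    return results


def expression_ratio_from_table(
    table: pd.DataFrame,
    target: str,
    reference: str,
    efficiency: float = 2.0,
    tolerance: float = 0.5,
) -> tuple[float, dict[str, RelativeExpression]]:
    """Per-sample target/reference ratios and their geometric-mean combination.

    For each sample, technical-duplicate Cq values of target and reference are
    averaged on the Cq scale before the ratio is formed; no-RT rows are
    excluded. Returns (combined ratio, per-sample RelativeExpression).
    """
    validate_cq_table(table)
    templ = table[~table["is_no_rt"].astype(bool)]
    per_sample: dict[str, RelativeExpression] = {}
    for sample, grp in templ.groupby("sample"):
        tcq = grp.loc[grp["target"] == target, "cq"].astype(float).tolist()
        rcq = grp.loc[grp["target"] == reference, "cq"].astype(float).tolist()
        if not tcq or not rcq:
            raise ValueError(
                f"sample {sample!r} lacks Cq rows for {target!r} or {reference!r}"
            )
        per_sample[str(sample)] = relative_expression(
            mean_cq(tcq, tolerance).value, mean_cq(rcq, tolerance).value, efficiency
        )
    if not per_sample:
        raise ValueError("no template rows in table")
    combined = math.exp(
        sum(math.log(r.ratio) for r in per_sample.values()) / len(per_sample)
    )
    return combined, per_sample
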