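"""Synonymous codon recoding (alternative-codon-usage design).

The design problem: rewrite a coding sequence so that every codon that *can*
be changed without altering the encoded protein *is* changed, while leaving
designated sequence segments (e.g. preserved intron junctions, cloning sites)
untouched. The recoded RNA carries the same protein but loses sequence-level
cis-elements, which is the point of an alternative-codon-usage (ACU) allele.

Two replacement policies are provided:

* ``max-frequency-alternative`` — deterministic: each replaceable codon is
  swapped for the most frequently used synonymous codon other than itself
  (ties broken lexicographically).
* ``usage-weighted-sample`` — seeded sampling of the replacement from the
  synonymous family, weighted by codon-usage frequency renormalized after
  excluding the original codon.

Codon-usage frequencies are an input (a table shipped for *Drosophila
melanogaster* is available via :func:`load_dmel_usage`), never hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "CdsSequence",
    "ProtectedIntervals",
    "TranslationResult",
    "RecodeResult",
    "translate",
    "recode_cds",
    "nucleotide_identity",
    "load_dmel_usage",
]

_BASES = frozenset("ACGT")
STOP = "*"


class FrameError(ValueError):
    """CDS length is not a multiple of 3."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class GeneticCode:
    """Codon → amino-acid mapping; stop codons map to ``'*'``.

    Exactly 64 codons, exactly 3 stops for the standard code.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ValueError(f"genetic code must define 64 codons, got {len(self.mapping)}")
        stops = [c for c, aa in self.mapping.items() if aa == STOP]
        if len(stops) != 3:
            raise ValueError(f"expected 3 stop codons, got {len(stops)}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(mapping=mapping)

    def family(self, amino_acid: str) -> tuple[str, ...]:
        """All codons encoding ``amino_acid``, sorted lexicographically."""
        return tuple(sorted(c for c, aa in self.mapping.items() if aa == amino_acid))

    def __getitem__(self, codon: str) -> str:
        return self.mapping[codon]


STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous-codon frequencies, keyed by codon.

    Within each synonymous family the frequencies sum to 1 (±1e-9); all 64
    codons must be present and nonnegative.
    """

    frequencies: Mapping[str, float]
    code: GeneticCode = field(default=STANDARD_CODE)

    def __post_init__(self) -> None:
        missing = set(self.code.mapping) - set(self.frequencies)
        if missing:
            raise ValueError(f"usage table missing codons: {sorted(missing)[:5]} ...")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("codon usage frequencies must be nonnegative")
        for aa in set(self.code.mapping.values()):
            fam = self.code.family(aa)
            total = sum(self.frequencies[c] for c in fam)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"frequencies for family {aa} ({fam}) sum to {total!r}, expected 1"
                )

    @classmethod
    def from_tsv(cls, path, code: GeneticCode = STANDARD_CODE) -> "CodonUsageTable":
        """Read a TSV with columns codon, amino_acid, relative_frequency."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"codon": str})
        required = {"codon", "amino_acid", "relative_frequency"}
        if not required.issubset(df.columns):
            raise ValueError(f"usage TSV needs columns {sorted(required)}")
        freqs = {}
        for row in df.itertuples(index=False):
            codon = row.codon.upper()
            if code[codon] != row.amino_acid:
                raise ValueError(
                    f"codon {codon} annotated as {row.amino_acid} but code says {code[codon]}"
                )
            freqs[codon] = float(row.relative_frequency)
        return cls(frequencies=freqs, code=code)

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[codon]


def load_dmel_usage() -> CodonUsageTable:
    """The shipped *D. melanogaster* codon-usage table."""
    ref = resources.files("slamkit.data").joinpath("dmel_codon_usage.tsv")
    with resources.as_file(ref) as path:
        return CodonUsageTable.from_tsv(path)


@dataclass(frozen=True)
class CdsSequence:
    """A coding sequence: id plus an uppercase A/C/G/T string, length % 3 == 0.

    Internal stop codons are tolerated with a warning (they occur by design in
    constructs such as GFP-stop fusions).
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _BASES
        if bad:
            raise AlphabetError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        if len(self.seq) % 3 != 0:
            raise FrameError(f"{self.id}: length {len(self.seq)} not divisible by 3")

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def __len__(self) -> int:
        return len(self.seq)


class ProtectedIntervals:
    """0-based half-open [start, end) intervals of a CDS that must not change.

    Overlapping/adjacent intervals are merged. Intervals that are not
    codon-aligned are expanded outward to the covering codon boundaries (with
    a warning): conservative, protected bases are never mutated.
    """

    def __init__(self, intervals: Iterable[tuple[int, int]] = ()) -> None:
        ivs = sorted((int(s), int(e)) for s, e in intervals)
        for s, e in ivs:
            if s < 0 or e < s:
                raise ValueError(f"invalid interval [{s}, {e})")
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.intervals: list[tuple[int, int]] = [(s, e) for s, e in merged]

    def check_bounds(self, seq_len: int) -> None:
        for s, e in self.intervals:
            if e > seq_len:
                raise ValueError(f"interval [{s}, {e}) exceeds CDS length {seq_len}")

    def protected_codons(self, n_codons: int) -> set[int]:
        """Codon indices covered after expansion to codon boundaries."""
        out: set[int] = set()
        for s, e in self.intervals:
            if s % 3 or e % 3:
                warnings.warn(
                    f"protected interval [{s}, {e}) is not codon-aligned; "
                    "expanding to covering codon boundaries",
                    stacklevel=2,
                )
            first = s // 3
            last = (e + 2) // 3  # ceil
            out.update(range(first, min(last, n_codons)))
        return out

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class TranslationResult:
    """Protein string up to (excluding) the first stop, plus stop bookkeeping."""

    protein: str
    stop_index: int | None  # codon index of the first stop, if any
    trailing_stop: bool  # the first stop is the last codon


@dataclass(frozen=True)
class RecodeResult:
    recoded: CdsSequence
    changed_codon_count: int
    nucleotide_identity: float
    per_codon_log: list[tuple[int, str, str]]  # (codon index, old, new)


def translate(cds: CdsSequence, code: GeneticCode = STANDARD_CODE) -> TranslationResult:
    """Translate a CDS codon-by-codon, stopping at the first stop codon."""
    codons = cds.codons()
    protein = []
    stop_index = None
    for i, codon in enumerate(codons):
        aa = code[codon]
        if aa == STOP:
            stop_index = i
            break
        protein.append(aa)
    return TranslationResult(
        protein="".join(protein),
        stop_index=stop_index,
        trailing_stop=stop_index is not None and stop_index == len(codons) - 1,
    )


def _full_translation(codons: Sequence[str], code: GeneticCode) -> tuple[str, ...]:
    """Codon-for-codon amino-acid tuple, stops included (for invariant checks)."""
    return tuple(code[c] for c in codons)


POLICIES = ("max-frequency-alternative", "usage-weighted-sample")


def recode_cds(
    cds: CdsSequence,
    usage: CodonUsageTable,
    protected: ProtectedIntervals | Iterable[tuple[int, int]] = (),
    policy: str = "max-frequency-alternative",
    seed: int = 0,
) -> RecodeResult:
    """Replace every replaceable codon with a different synonymous codon.

    A codon is replaceable iff its synonymous family has ≥2 members, it is not
    a stop codon, and it does not fall in a protected interval. Met (ATG) and
    Trp (TGG) are single-codon families and therefore never change; stop
    codons (including internal ones, which draw a warning) are left unchanged.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}, got {policy!r}")
    if not isinstance(protected, ProtectedIntervals):
        protected = ProtectedIntervals(protected)
    protected.check_bounds(len(cds))
    code = usage.code
    codons = cds.codons()
    mask = protected.protected_codons(len(codons))
    rng = np.random.default_rng(seed)

    new_codons: list[str] = []
    log: list[tuple[int, str, str]] = []
    for i, codon in enumerate(codons):
        aa = code[codon]
        if aa == STOP and i < len(codons) - 1:
            warnings.warn(
                f"{cds.id}: internal stop codon {codon} at codon {i}; left unchanged",
                stacklevel=2,
            )
        family = code.family(aa)
        alternatives = [c for c in family if c != codon]
        if i in mask or aa == STOP or not alternatives:
            new_codons.append(codon)
            continue
        if policy == "max-frequency-alternative":
            # max() keeps the first of equals; alternatives are sorted, so ties
            # resolve to the lexicographically smallest codon
            replacement = max(alternatives, key=lambda c: usage[c])
        else:
            weights = np.array([usage[c] for c in alternatives], dtype=float)
            if weights.sum() <= 0:
                raise ValueError(
                    f"usage frequencies for alternatives of {codon} are all zero"
                )
            replacement = alternatives[rng.choice(len(alternatives), p=weights / weights.sum())]
        new_codons.append(replacement)
        log.append((i, codon, replacement))

    recoded = CdsSequence(id=f"{cds.id}_ACU", seq="".join(new_codons))
    assert _full_translation(recoded.codons(), code) == _full_translation(codons, code)
    return RecodeResult(
        recoded=recoded,
        changed_codon_count=len(log),
        nucleotide_identity=nucleotide_identity(cds, recoded),
        per_codon_log=log,
    )


def nucleotide_identity(a: CdsSequence, b: CdsSequence) -> float:
    """Fraction of positions with identical bases; sequences must align 1:1."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        return 1.0
    matches = sum(x == y for x, y in zip(a.seq, b.seq))
    return matches / len(a)
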