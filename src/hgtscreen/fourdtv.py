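"""4DTv: transversion proportion at fourfold-degenerate third codon positions.

The statistic is a classical proxy for neutral nucleotide divergence between
two in-frame aligned coding sequences: among codon columns whose first two
positions are identical in both sequences and define a fourfold-degenerate
codon family, it is the fraction at which the third positions differ by a
transversion (purine <-> pyrimidine).  No model-based correction is applied;
the raw proportion is reported.

Also provided: reciprocal-best-hit (RBH) one-to-one orthologue pairing from
directional similarity-hit tables, and an empirical confidence-interval
membership test of candidate pairs against the genome-wide orthologue
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import HitRecord, ValidationError

#: two-base codon prefixes whose third position is fourfold degenerate
#: (standard genetic code): Leu(CTN), Val(GTN), Ser(TCN), Pro(CCN), Thr(ACN),
#: Ala(GCN), Arg(CGN), Gly(GGN)
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_NUCS = frozenset("ACGT-")


@dataclass(frozen=True)
class CodonPairAlignment:
    """Two equal-length, in-frame, gap-aligned CDS sequences.

    The frame is anchored at position 0 and gaps may occur only in
    whole-codon units; both constraints are enforced on construction because
    4DTv is undefined across frameshifts.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValidationError(
                f"aligned sequences differ in length ({len(a)} vs {len(b)})"
            )
        if len(a) % 3:
            raise ValidationError(f"alignment length {len(a)} not a multiple of 3")
        for name, seq in (("seq_a", a), ("seq_b", b)):
            bad = set(seq) - _NUCS
            if bad:
                raise ValidationError(f"{name} contains invalid characters {bad}")
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValidationError(
                        f"{name}: gap not in whole-codon units at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class FourDTvResult:
    """Count of fourfold-degenerate sites scored and transversions among them."""

    n_sites: int
    n_transversions: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_transversions <= self.n_sites:
            raise ValidationError(
                f"n_transversions {self.n_transversions} outside "
                f"[0, {self.n_sites}]"
            )

    @property
    def value(self) -> float | None:
        """Transversion proportion, or None when no site could be scored."""
        if self.n_sites == 0:
            return None
        return self.n_transversions / self.n_sites


def _codon_arrays(pair: CodonPairAlignment) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(pair.seq_a.encode("ascii"), dtype=np.uint8).reshape(-1, 3)
    b = np.frombuffer(pair.seq_b.encode("ascii"), dtype=np.uint8).reshape(-1, 3)
    return a, b


_PREFIX_CODES = frozenset(
    (ord(p[0]) << 8) | ord(p[1]) for p in FOURFOLD_PREFIXES
)
_PREFIX_CODE_ARR = np.array(sorted(_PREFIX_CODES), dtype=np.int32)
_GAP = ord("-")
_PURINE_CODES = np.array([ord("A"), ord("G")], dtype=np.uint8)


def _fourfold_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mask over codons scoring as fourfold-degenerate sites."""
    no_gap = ~np.any(a == _GAP, axis=1) & ~np.any(b == _GAP, axis=1)
    prefix_equal = (a[:, 0] == b[:, 0]) & (a[:, 1] == b[:, 1])
    code = (a[:, 0].astype(np.int32) << 8) | a[:, 1].astype(np.int32)
    fourfold = np.isin(code, _PREFIX_CODE_ARR)
    return no_gap & prefix_equal & fourfold


def fourfold_sites(pair: CodonPairAlignment) -> list[int]:
    """Codon indices scored as fourfold-degenerate sites.

    A codon column qualifies when (i) neither codon contains a gap, (ii) the
    first two positions are identical between the sequences, and (iii) that
    shared prefix belongs to a fourfold-degenerate family.  The third
    position may differ.
    """
    a, b = _codon_arrays(pair)
    return np.flatnonzero(_fourfold_mask(a, b)).tolist()


def fourdtv(pair: CodonPairAlignment) -> FourDTvResult:
    """Compute the 4DTv statistic for one aligned CDS pair.

    Transitions (A<->G, C<->T) and identical third positions contribute to
    the denominator only; transversions to both.
    """
    a, b = _codon_arrays(pair)
    mask = _fourfold_mask(a, b)
    third_a, third_b = a[mask, 2], b[mask, 2]
    pur_a = np.isin(third_a, _PURINE_CODES)
    pur_b = np.isin(third_b, _PURINE_CODES)
    n_tv = int(np.count_nonzero(pur_a != pur_b))
    return FourDTvResult(n_sites=int(np.count_nonzero(mask)), n_transversions=n_tv)


# ---------------------------------------------------------------------------
# reciprocal best hits


def _unique_best(hits: Iterable[HitRecord]) -> dict[str, str]:
    """Map each query to its unique top-bitscore subject; ties disqualify."""
    best: dict[str, tuple[float, str, bool]] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur[0]:
            best[h.query_id] = (h.bitscore, h.subject_id, False)
        elif h.bitscore == cur[0] and h.subject_id != cur[1]:
            best[h.query_id] = (cur[0], cur[1], True)  # tie -> disqualified
    return {q: s for q, (score, s, tied) in best.items() if not tied}


def one_to_one_pairs(
    hits_ab: Iterable[HitRecord], hits_ba: Iterable[HitRecord]
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit one-to-one orthologue pairs.

    Returns sorted pairs (a, b) such that b is a's unique top-bitscore hit
    in ``hits_ab`` and a is b's unique top-bitscore hit in ``hits_ba``.
    A tie for either top score disqualifies the gene.
    """
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)


# ---------------------------------------------------------------------------
# confidence-interval membership


def ci_membership_test(
    candidates: Sequence[FourDTvResult],
    background: Sequence[FourDTvResult],
    alpha: float = 0.05,
    method: str = "percentile",
) -> list[str | None]:
    """Test whether candidate 4DTv values fall inside the background CI.

    The default interval is the empirical [alpha/2, 1 - alpha/2] percentile
    interval of the background values (undefined values dropped); a
    normal-approximation interval is available with ``method="normal"``.
    Returns "inside"/"outside" per candidate, or None for candidates whose
    4DTv is undefined.
    """
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha {alpha} outside (0, 0.5)")
    values = np.array(
        [r.value for r in background if r.value is not None], dtype=float
    )
    if values.size < 20:
        raise ValidationError(
            f"background too small: {values.size} defined values (need >= 20)"
        )
    if method == "percentile":
        lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif method == "normal":
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = values.mean() - z * values.std(ddof=1)
        hi = values.mean() + z * values.std(ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    out: list[str | None] = []
    for cand in candidates:
        if cand.value is None:
            out.append(None)
        else:
            out.append("inside" if lo <= cand.value <= hi else "outside")
    return out
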