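"""Reconstruct integer count vectors from printed summary statistics.

Clinical papers typically report per-group count data only as a handful of
summary rows (n, mean, SD, median, range, sometimes a detection rate or a
specificity at a fixed cutoff), all rounded to one decimal.  For small n and
a narrow value range the set of integer multisets consistent with those
summaries is finite and can be enumerated exhaustively.  When the set is a
singleton the raw data are fully recoverable from the printed table; when it
is not, any member is an admissible witness and only constraint-implied
quantities (e.g. the number of positive patients) may be treated as facts.

The search enumerates sorted (non-increasing) integer vectors with pruning on
partial sums and sums of squares, so it is deterministic and works on
multisets — permutations of the same vector are never visited twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional

__all__ = ["CountConstraints", "ReconstructionResult", "reconstruct_counts", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), the convention of
    clinical summary tables, rather than banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountConstraints:
    """Printed summary constraints on an integer count vector.

    Parameters
    ----------
    n : number of subjects in the group.
    vmin, vmax : printed range; both endpoints must be attained when
        ``require_range_attained`` is True (the default), since the printed
        "Range (min-max)" row reports observed extremes.
    mean, sd : printed group mean and sample SD (n-1 denominator), both at
        ``decimals`` decimal places under half-up rounding.
    median : optional printed median (checked at the same precision).
    n_positive : optional number of entries >= 1, implied by a printed
        detection rate or a specificity at the one-cell cutoff.
    """

    n: int
    vmin: int
    vmax: int
    mean: float
    sd: float
    median: Optional[float] = None
    n_positive: Optional[int] = None
    decimals: int = 1
    require_range_attained: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.vmin > self.vmax:
            raise ValueError("vmin must be <= vmax")

    def rounding_matches(self, values) -> bool:
        """True iff a concrete vector reproduces the printed mean/SD/range."""
        vals = sorted(values)
        if vals[0] < self.vmin or vals[-1] > self.vmax:
            return False
        if self.require_range_attained and (vals[0] != self.vmin or vals[-1] != self.vmax):
            return False
        n = len(vals)
        mean = sum(vals) / n
        if round_half_up(mean, self.decimals) != self.mean:
            return False
        if n > 1:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            if round_half_up(math.sqrt(var), self.decimals) != self.sd:
                return False
        return True


@dataclass
class ReconstructionResult:
    """All multisets compatible with a :class:`CountConstraints`."""

    candidates: list[tuple[int, ...]] = field(default_factory=list)
    constraints: Optional[CountConstraints] = None
    truncated: bool = False

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1 and not self.truncated

    @property
    def witness(self) -> tuple[int, ...]:
        """First candidate in the deterministic enumeration order
        (descending-lexicographic over sorted vectors)."""
        return self.candidates[0]


def _half_ulp(decimals: int) -> Fraction:
    return Fraction(1, 10**decimals) / 2


def _as_frac(x: float) -> Fraction:
    return Fraction(Decimal(repr(x)))


def reconstruct_counts(c: CountConstraints, max_candidates: Optional[int] = None) -> ReconstructionResult:
    """Enumerate every integer multiset satisfying the printed summaries.

    Candidates are returned as non-increasing tuples in descending
    lexicographic order.  ``max_candidates`` truncates the search (the
    result is then flagged ``truncated`` unless the search finished early).

    Raises
    ------
    ValueError
        If no multiset satisfies the constraints ("constraints inconsistent").
    """
    n, vmin, vmax = c.n, c.vmin, c.vmax
    h = _half_ulp(c.decimals)
    mean_t, sd_t = _as_frac(c.mean), _as_frac(c.sd)

    # integer sums whose mean rounds to the printed value
    sum_lo = math.ceil((mean_t - h) * n)
    sum_hi = math.ceil((mean_t + h) * n) - 1
    sums = [s for s in range(sum_hi, sum_lo - 1, -1) if n * vmin <= s <= n * vmax]

    # corrected-sum-of-squares band from the printed SD
    css_lo = max(sd_t - h, Fraction(0)) ** 2 * (n - 1) if n > 1 else Fraction(0)
    css_hi = (sd_t + h) ** 2 * (n - 1) if n > 1 else Fraction(1)

    results: list[tuple[int, ...]] = []
    truncated = False

    for total in sums:
        # sum(x^2) band given this total
        sq_lo = css_lo + Fraction(total * total, n)
        sq_hi = css_hi + Fraction(total * total, n)
        vec: list[int] = []

        def leaf_ok(t: tuple[int, ...]) -> bool:
            if c.require_range_attained and (t[0] != vmax or t[-1] != vmin):
                return False
            if c.median is not None:
                asc = t[::-1]
                med = (Fraction(asc[n // 2 - 1] + asc[n // 2], 2) if n % 2 == 0
                       else Fraction(asc[n // 2]))
                if not (_as_frac(c.median) - h <= med < _as_frac(c.median) + h):
                    return False
            if c.n_positive is not None and sum(1 for v in t if v >= 1) != c.n_positive:
                return False
            return True

        def recurse(k: int, rem_sum: int, cap: int, sq_have: int) -> None:
            nonlocal truncated
            if max_candidates is not None and len(results) >= max_candidates:
                truncated = True
                return
            if k == 0:
                if rem_sum == 0 and sq_lo <= Fraction(sq_have) < sq_hi:
                    t = tuple(vec)
                    if leaf_ok(t):
                        results.append(t)
                return
            v_hi = min(cap, rem_sum - (k - 1) * vmin)
            v_lo = max(vmin, -(-rem_sum // k))  # ceil(rem_sum / k): keep non-increasing
            for v in range(v_hi, v_lo - 1, -1):
                rs = rem_sum - v
                kk = k - 1
                sq_new = sq_have + v * v
                # prune on achievable tail sum of squares
                min_tail = Fraction(rs * rs, kk) if kk else Fraction(0)
                max_tail = Fraction(_max_tail_sq(kk, rs, v, vmin))
                if Fraction(sq_new) + min_tail >= sq_hi or Fraction(sq_new) + max_tail < sq_lo:
                    continue
                vec.append(v)
                recurse(kk, rs, v, sq_new)
                vec.pop()
                if max_candidates is not None and len(results) >= max_candidates:
                    truncated = True
                    return

        recurse(n, total, vmax, 0)
        if truncated:
            break

    if not results:
        raise ValueError("constraints inconsistent: no integer multiset matches the printed summaries")
    return ReconstructionResult(candidates=results, constraints=c, truncated=truncated)


def _max_tail_sq(k: int, rem_sum: int, cap: int, vmin: int) -> int:
    """Max of sum(x^2) over k integers in [vmin, cap] with fixed sum
    (concentrate mass at the cap, remainder in a single slot)."""
    if k == 0:
        return 0
    if cap == vmin:
        return k * cap * cap
    n_cap = min(k, (rem_sum - k * vmin) // (cap - vmin))
    total = n_cap * cap * cap
    if n_cap < k:
        rest = rem_sum - n_cap * cap - (k - n_cap - 1) * vmin
        total += rest * rest + (k - n_cap - 1) * vmin * vmin
    return total
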