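"""Quality-ranked partial-validation extrapolation.

When only a subset of variant candidates is re-sequenced (Sanger style),
and candidates are ranked by caller quality, a clean outcome pattern —
confirmations above a block of failures — locates a quality boundary: the
number of truly existing variants is taken as the number of candidates
ranked strictly above the best-ranked failure.  Validating the 12
lowest-quality of 45 homozygous candidates and finding the bottom 6 absent
estimates 39 true ones; validating the 48 highest-quality of 121
heterozygous candidates and confirming only the top 13 estimates 13.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mendel import fixation_probabilities


@dataclass
class RankedValidation:
    """Validation outcomes over quality-ranked candidates.

    Ranks are 1-based, rank 1 = highest caller quality.  ``outcomes`` maps
    the rank of each validated candidate to True (confirmed by
    re-sequencing) or False (not detected).
    """

    n_candidates: int
    outcomes: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_candidates < 0:
            raise ValueError("n_candidates must be >= 0")
        for rank in self.outcomes:
            if not 1 <= rank <= self.n_candidates:
                raise ValueError(f"validated rank {rank} outside 1..{self.n_candidates}")


def estimate_true_count(rv: RankedValidation) -> int:
    """Estimated number of truly existing candidates.

    With a consistent outcome ordering (no confirmation ranked below a
    failure's rank... i.e. failures form the bottom block of the validated
    subset), the estimate is the count of candidates ranked strictly above
    the best-ranked failure; with no failures at all, every candidate is
    kept.  If outcomes are inconsistent the boundary falls back to the
    lowest-ranked confirmation.
    """
    if rv.n_candidates == 0:
        return 0
    failures = sorted(r for r, ok in rv.outcomes.items() if not ok)
    confirms = sorted(r for r, ok in rv.outcomes.items() if ok)
    if not failures:
        return rv.n_candidates
    best_failure = failures[0]
    if confirms and confirms[-1] > best_failure:
        # mixed ordering: trust confirmations down to the lowest-ranked one
        return confirms[-1]
    return best_failure - 1


def consistency_ratio(
    homo_estimate: float, het_estimate: float, g: int
) -> tuple[float | None, float]:
    """Observed hom/het estimate ratio next to the selfing expectation.

    Returns ``(observed, expected)`` where expected = p_hom(g)/p_het(g);
    the comparison is qualitative (no test statistic).  ``observed`` is
    None when the heterozygous estimate is zero.
    """
    prof = fixation_probabilities(g)
    if prof.p_het == 0:
        raise ValueError("p_het is zero; expected ratio undefined")
    expected = prof.p_hom / prof.p_het
    observed = None if het_estimate == 0 else homo_estimate / het_estimate
    return observed, expected
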