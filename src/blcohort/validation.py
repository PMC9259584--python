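"""Reconciliation of pipeline calls against an orthogonal (Sanger) call set.

Within regions covered by both technologies, calls from the two sources are
matched by normalized variant key and partitioned into: exact matches,
matches after representation review (raw strings differed but normalize to
the same key), calls discovered by both but removed by the somatic filter
hierarchy (confirmed filtered), hard false negatives (orthogonal-only), and
false positives (pipeline-only).  Sensitivity/specificity are reported in
two conventions: the operational one using the union count as denominator,
and the classical TP-based one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .filtering import normalize_variant_key

__all__ = ["SangerCall", "PipelineCall", "ReconciliationReport", "reconcile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SangerCall:
    chrom: str
    pos: int
    ref: str
    alt: str

    def key(self):
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PipelineCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    filtered: bool = False  # discovered but removed by the filter hierarchy

    def key(self):
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ReconciliationReport:
    """Concordance accounting between two call sets in covered regions.

    ``sensitivity``/``specificity`` use the union of calls (``n_total``) as
    denominator (operational definitions); ``classical_sensitivity`` is
    TP / (TP + FN) over unfiltered pipeline calls.
    """

    n_total: int
    n_match: int
    n_match_after_review: int
    n_filtered_confirmed: int
    n_hard_fn: int
    n_fp: int
    n_excluded_outside_regions: int = 0

    def __post_init__(self):
        parts = (
            self.n_match
            + self.n_match_after_review
            + self.n_filtered_confirmed
            + self.n_hard_fn
            + self.n_fp
        )
        if parts != self.n_total:
            raise ValueError(
                f"categories sum to {parts}, expected n_total={self.n_total}"
            )

    @property
    def fn_rate(self) -> float:
        return self.n_hard_fn / self.n_total

    @property
    def sensitivity(self) -> float:
        return 1.0 - self.fn_rate

    @property
    def fp_rate(self) -> float:
        return self.n_fp / self.n_total

    @property
    def specificity(self) -> float:
        return 1.0 - self.fp_rate

    @property
    def classical_sensitivity(self) -> float:
        tp = self.n_match + self.n_match_after_review
        denom = tp + self.n_hard_fn
        return tp / denom if denom else float("nan")

    def summary(self) -> str:
        return (
            f"{self.n_total} variants in covered regions: "
            f"{self.n_match} matches + {self.n_match_after_review} after review, "
            f"{self.n_filtered_confirmed} confirmed filtered, "
            f"{self.n_hard_fn} hard FN, {self.n_fp} FP | "
            f"sensitivity {self.sensitivity:.3f}, specificity {self.specificity:.3f}"
        )


def _in_regions(key, covered_regions) -> bool:
    chrom, pos = key[0], key[1]
    for r_chrom, start, end in covered_regions:
        # BED-style 0-based half-open interval against 1-based position
        if r_chrom == chrom and start < pos <= end:
            return True
    return False


def reconcile(sanger_calls, pipeline_calls, covered_regions=None) -> ReconciliationReport:
    """Partition two call sets into concordance categories by normalized key.

    ``covered_regions`` is an iterable of BED-style ``(chrom, start, end)``
    intervals; calls outside them are excluded with a logged count.  When
    ``None``, all calls are considered covered.  Pipeline calls flagged
    ``filtered`` count only when the orthogonal set confirms the site
    (confirmed-filtered category); filtered-only calls are not part of the
    reconciliation universe.
    """
    n_excluded = 0

    def keep(call):
        nonlocal n_excluded
        if covered_regions is None or _in_regions(call.key(), covered_regions):
            return True
        n_excluded += 1
        return False

    sanger = [c for c in sanger_calls if keep(c)]
    pipe = [c for c in pipeline_calls if keep(c)]
    if n_excluded:
        logger.info("excluded %d calls outside covered regions", n_excluded)

    sanger_keys = {c.key() for c in sanger}
    sanger_raw = {(c.chrom, c.pos, c.ref.upper(), c.alt.upper()) for c in sanger}
    pipe_called = {c.key(): c for c in pipe if not c.filtered}
    pipe_filtered = {c.key() for c in pipe if c.filtered}

    n_match = n_review = n_fp = 0
    for key, call in pipe_called.items():
        if key in sanger_keys:
            raw = (call.chrom, call.pos, call.ref.upper(), call.alt.upper())
            if raw in sanger_raw:
                n_match += 1
            else:
                n_review += 1  # same event, representations differed
        else:
            n_fp += 1
    n_filtered_confirmed = len(pipe_filtered & (sanger_keys - set(pipe_called)))
    n_hard_fn = len(sanger_keys - set(pipe_called) - pipe_filtered)
    n_total = n_match + n_review + n_filtered_confirmed + n_hard_fn + n_fp

    return ReconciliationReport(
        n_total=n_total,
        n_match=n_match,
        n_match_after_review=n_review,
        n_filtered_confirmed=n_filtered_confirmed,
        n_hard_fn=n_hard_fn,
        n_fp=n_fp,
        n_excluded_outside_regions=n_excluded,
    )
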