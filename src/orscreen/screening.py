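"""Library-screen analysis: normalization, 2-sigma hit calling, false positives.

Raw screen processing follows the published scheme: per well, the three basal
and three post-stimulus luminescence reads are each averaged and the basal
mean subtracted; each well's signal is divided by the summarized signal of
the plate's positive-control wells (OR1A1 vs 30 umol/L R-(-)-carvone);
normalized duplicate wells of each receptor are then averaged. A receptor is
a hit when its normalized signal strictly exceeds the screen-wide threshold
mean + 2*SD computed over all test-receptor values (mock and positive
control excluded; the mock signal is reported alongside). Hits that later
fail concentration-response validation are classified as false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    IncompleteValidationError,
    InsufficientDataError,
    MalformedRecordError,
)
from .records import WellRecord

log = logging.getLogger(__name__)


def summarize_well(well) -> float:
    """Basal-subtracted signal of one well: mean(post) - mean(basal).

    Accepts a :class:`WellRecord` or a plate-table row (mapping/Series with
    ``basal_1..3`` and ``post_1..3``). May be negative.
    """
    if isinstance(well, WellRecord):
        basal, post = well.basal_reads, well.post_reads
    else:
        try:
            basal = [well[f"basal_{i}"] for i in (1, 2, 3)]
            post = [well[f"post_{i}"] for i in (1, 2, 3)]
        except (KeyError, TypeError) as exc:
            raise MalformedRecordError(f"well record missing reads: {exc}") from exc
        if any(pd.isna(v) for v in (*basal, *post)):
            raise MalformedRecordError("well record has missing reads")
    return float(np.mean(post) - np.mean(basal))


def delta_signals(wells: pd.DataFrame) -> pd.Series:
    """Vectorized well summaries for a plate table."""
    basal = wells[["basal_1", "basal_2", "basal_3"]].mean(axis=1)
    post = wells[["post_1", "post_2", "post_3"]].mean(axis=1)
    return post - basal


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of 2-sigma hit calling over one screen."""

    normalized: pd.Series  # variant -> normalized RLU (duplicates averaged)
    screen_mean: float
    screen_sd: float
    threshold_2sigma: float
    hits: frozenset[str]
    mock_rlu: float
    sd_convention: str
    false_positives: frozenset[str] | None = None
    fp_fraction: float | None = None

    @property
    def n_variants(self) -> int:
        return len(self.normalized)


def normalize_screen(wells: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-plate positive-control normalization, then duplicate averaging.

    Returns ``(values, mock_rlu)``: the per-variant normalized responses and
    the mean normalized mock signal. Raises
    :class:`~orscreen.errors.DegenerateReferenceError` naming the plate when a
    positive-control summarized signal is not strictly positive.
    """
    d = wells.copy()
    d["delta"] = delta_signals(d)

    pos = d[d["role"] == "positive"]
    ref = pos.groupby("plate_id")["delta"].mean()
    plates = d["plate_id"].unique()
    missing = [p for p in plates if p not in ref.index]
    if missing:
        raise DegenerateReferenceError(f"plates without positive control: {missing}")
    bad = ref[ref <= 0]
    if not bad.empty:
        raise DegenerateReferenceError(
            f"non-positive positive-control signal on plate(s) {list(bad.index)}"
        )
    d["norm"] = d["delta"] / d["plate_id"].map(ref)

    tests = d[d["role"] == "test"]
    counts = tests.groupby("variant_id").size()
    if counts.nunique() > 1:
        log.warning(
            "unequal duplicate counts across variants (%d..%d); averaging available wells",
            counts.min(), counts.max(),
        )
    values = tests.groupby("variant_id")["norm"].mean()
    mock = d[d["role"] == "mock"]["norm"]
    mock_rlu = float(mock.mean()) if len(mock) else float("nan")
    return values, mock_rlu


def call_hits(
    normalized: Mapping[str, float] | pd.Series,
    sd_convention: str = "sample",
    mock_rlu: float = float("nan"),
) -> ScreenResult:
    """Flag receptors whose normalized signal strictly exceeds mean + 2*SD.

    The mean and SD are computed over all test-receptor values (hits
    included). ``sd_convention`` selects sample (n-1, default) or population
    (n) standard deviation.
    """
    values = pd.Series(normalized, dtype=float).sort_index()
    if len(values) < 2:
        raise InsufficientDataError("need >= 2 variants to define the 2-sigma threshold")
    if sd_convention not in ("sample", "population"):
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    ddof = 1 if sd_convention == "sample" else 0
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof))
    threshold = mean + 2.0 * sd
    hits = frozenset(values.index[values > threshold])
    return ScreenResult(
        normalized=values,
        screen_mean=mean,
        screen_sd=sd,
        threshold_2sigma=threshold,
        hits=hits,
        mock_rlu=mock_rlu,
        sd_convention=sd_convention,
    )


def classify_false_positives(
    result: ScreenResult, validations: Mapping[str, bool]
) -> ScreenResult:
    """Split hits by concentration-response validation outcome.

    ``validations`` must cover every hit; hits whose validation is False
    (no concentration-dependent activation) become false positives, and the
    false-positive fraction is their count over all screened receptors.
    """
    missing = [h for h in result.hits if h not in validations]
    if missing:
        raise IncompleteValidationError(f"hits without validation outcome: {sorted(missing)}")
    fps = frozenset(h for h in result.hits if not validations[h])
    return replace(
        result,
        false_positives=fps,
        fp_fraction=len(fps) / result.n_variants,
    )


def run_screen(
    wells: pd.DataFrame,
    sd_convention: str = "sample",
    validations: Mapping[str, bool] | None = None,
) -> ScreenResult:
    """Full screen pipeline: normalize, average duplicates, call hits.

    When ``validations`` is given, hits are additionally classified into
    validated hits and false positives.
    """
    values, mock_rlu = normalize_screen(wells)
    result = call_hits(values, sd_convention=sd_convention, mock_rlu=mock_rlu)
    if validations is not None:
        result = classify_false_positives(result, validations)
    return result
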