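"""Internal-standard quantification of headspace aldehydes.

Fly headspace rinses are spiked with 100 ng decanal; with a unit response
factor, the amount of an analyte is

    amount_ng = is_ng * area(analyte) / area(internal standard).

The strain-level statistic is the per-sample Z4-9Al / Z4-11Al fold ratio,
summarized as arithmetic mean +/- sample SD over batches (the per-sample
formulation is what the reported "2.6 +/- 0.7-fold, n = 10" implies). The
internal standard cancels from the ratio, so the ratio is invariant to
rescaling a sample's areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, InsufficientDataError, UndefinedRatioError

#: Default single-point calibration: equal detector response per ng for
#: analyte and internal standard. Configurable, but the published analysis
#: provides no per-analyte calibration curve.
DEFAULT_RESPONSE_FACTOR = 1.0

_AREA_COLUMNS = {"Z4-9Al": "area_z4_9al", "Z4-11Al": "area_z4_11al"}


def quantify(sample, analyte: str, response_factor: float = DEFAULT_RESPONSE_FACTOR) -> float:
    """Amount of ``analyte`` in ng by single-point internal-standard calibration.

    ``sample`` is a headspace-table row (mapping/Series with ``area_z4_9al``,
    ``area_z4_11al``, ``area_is``, ``is_ng``).
    """
    try:
        col = _AREA_COLUMNS[analyte]
    except KeyError:
        raise KeyError(f"unknown analyte {analyte!r}; expected one of {list(_AREA_COLUMNS)}")
    area_is = float(sample["area_is"])
    if area_is <= 0:
        raise DegenerateSampleError(
            f"sample {sample.get('sample_id', '?')}: internal-standard area {area_is} <= 0"
        )
    return float(sample["is_ng"]) * float(sample[col]) / area_is / response_factor


@dataclass(frozen=True)
class FoldRatioSummary:
    """Mean +/- sample SD of per-sample Z4-9Al/Z4-11Al ratios."""

    mean_ratio: float
    sd_ratio: float
    n: int


def quantify_table(samples: pd.DataFrame, response_factor: float = DEFAULT_RESPONSE_FACTOR) -> pd.DataFrame:
    """Per-sample quantified amounts and fold ratio.

    Returns columns sample_id, ng_z4_9al, ng_z4_11al, ratio.
    """
    if (samples["area_is"] <= 0).any():
        bad = samples.loc[samples["area_is"] <= 0, "sample_id"].tolist()
        raise DegenerateSampleError(f"non-positive internal-standard area in samples {bad}")
    out = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "ng_z4_9al": samples["is_ng"] * samples["area_z4_9al"] / samples["area_is"] / response_factor,
            "ng_z4_11al": samples["is_ng"] * samples["area_z4_11al"] / samples["area_is"] / response_factor,
        }
    )
    zero = out.loc[out["ng_z4_11al"] <= 0, "sample_id"].tolist()
    if zero:
        raise UndefinedRatioError(f"zero Z4-11Al amount in samples {zero}")
    out["ratio"] = out["ng_z4_9al"] / out["ng_z4_11al"]
    return out


def fold_ratio(samples: pd.DataFrame, response_factor: float = DEFAULT_RESPONSE_FACTOR) -> FoldRatioSummary:
    """Strain fold-ratio statistic over a batch of headspace samples."""
    if samples.empty:
        raise InsufficientDataError("no headspace samples")
    q = quantify_table(samples, response_factor=response_factor)
    ratios = q["ratio"].to_numpy()
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return FoldRatioSummary(mean_ratio=float(np.mean(ratios)), sd_ratio=sd, n=len(ratios))
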