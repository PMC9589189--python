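"""Plain-CSV schemas and readers/writers for every pipeline table.

All interchange is uncompressed CSV with fixed headers:

* plates: ``plate_id,well_id,variant_id,role,odorant,conc_umolL,
  basal_1,basal_2,basal_3,post_1,post_2,post_3`` (role in test/mock/positive)
* panel: ``panelist_id,or10a6_diplotype,or2w1_diplotype,trial_id,odorant,
  amount_ng,correct``
* headspace: ``sample_id,strain,area_z4_9al,area_z4_11al,area_is,is_ng``
* genotype calls: ``panelist_id,site,allele1,allele2``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import MalformedRecordError

PLATE_COLUMNS = [
    "plate_id", "well_id", "variant_id", "role", "odorant", "conc_umolL",
    "basal_1", "basal_2", "basal_3", "post_1", "post_2", "post_3",
]
PANEL_COLUMNS = [
    "panelist_id", "or10a6_diplotype", "or2w1_diplotype",
    "trial_id", "odorant", "amount_ng", "correct",
]
HEADSPACE_COLUMNS = [
    "sample_id", "strain", "area_z4_9al", "area_z4_11al", "area_is", "is_ng",
]
CALLS_COLUMNS = ["panelist_id", "site", "allele1", "allele2"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"{what} table missing columns: {missing}")
    return df[required]


def read_plates(paths: Iterable[str | Path] | str | Path) -> pd.DataFrame:
    """Read and concatenate one or more plate CSVs, validating the schema."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = [pd.read_csv(p) for p in paths]
    df = pd.concat(frames, ignore_index=True)
    df = _check_columns(df, PLATE_COLUMNS, "plate")
    from .records import check_plate_frame

    check_plate_frame(df)
    return df


def write_plates(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, PLATE_COLUMNS, "plate").to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), PANEL_COLUMNS, "panel")


def write_panel(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, PANEL_COLUMNS, "panel").to_csv(path, index=False)


def read_headspace(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), HEADSPACE_COLUMNS, "headspace")


def write_headspace(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, HEADSPACE_COLUMNS, "headspace").to_csv(path, index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), CALLS_COLUMNS, "genotype-calls")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def screen_result_frame(result) -> pd.DataFrame:
    """Tabular form of a :class:`~orscreen.screening.ScreenResult`."""
    fps = result.false_positives or frozenset()
    return pd.DataFrame(
        {
            "variant_id": result.normalized.index,
            "normalized_rlu": result.normalized.to_numpy(),
            "is_hit": [v in result.hits for v in result.normalized.index],
            "is_false_positive": [v in fps for v in result.normalized.index],
        }
    )


def screen_summary_dict(result) -> dict:
    return {
        "screen_mean": result.screen_mean,
        "screen_sd": result.screen_sd,
        "threshold": result.threshold_2sigma,
        "n_hits": len(result.hits),
        "fp_fraction": result.fp_fraction,
        "mock_rlu": result.mock_rlu,
        "sd_convention": result.sd_convention,
    }


def fits_frame(rows: list[dict]) -> pd.DataFrame:
    """Fit table with columns variant_id,odorant,replicate,min,max,ec50_umolL,hillslope,converged."""
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "odorant", "replicate",
            "min", "max", "ec50_umolL", "hillslope", "converged",
        ],
    )
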