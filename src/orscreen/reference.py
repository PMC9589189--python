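"""Reference constants: fitted receptor pharmacology, odorant chemistry.

``EC50_TABLE`` transcribes the published concentration-response summary for
the frequent OR10A6 and OR2W1 haplotypes against the three aldehydes
(mean +/- SD over n=3 transfections, umol/L; ``None`` = no response detected
up to 1000 umol/L). The generator treats these as ground truth when planting
responders.

Saturating amplitudes (fraction of the OR1A1 positive-control amplitude) and
Hill slopes are not published; the values below are the package's own
calibration, chosen once from the screening figures (OR10A6 L287P responds
near positive-control amplitude; OR2W1's raw Z4-11Al amplitude is about
six-fold lower; Z4-9Al amplitudes of the two receptors are comparable).
"""

from __future__ import annotations

from .errors import UnknownVariantError
from .records import ReceptorTruth

Z4_11AL = "Z4-11Al"
Z4_9AL = "Z4-9Al"
Z6_11AL = "Z6-11Al"
ALDEHYDES = (Z4_9AL, Z4_11AL, Z6_11AL)

#: (variant, odorant) -> (mean EC50 umol/L, SD) or None (no response <= 1000 umol/L)
EC50_TABLE: dict[tuple[str, str], tuple[float, float] | None] = {
    ("OR10A6 ref", Z4_9AL): None,
    ("OR10A6 ref", Z4_11AL): None,
    ("OR10A6 ref", Z6_11AL): None,
    ("OR10A6 L287P", Z4_9AL): (41.15, 14.24),
    ("OR10A6 L287P", Z4_11AL): (28.21, 12.65),
    ("OR10A6 L287P", Z6_11AL): (34.78, 9.21),
    ("OR10A6 A117V/V140G/L287P", Z4_9AL): None,
    ("OR10A6 A117V/V140G/L287P", Z4_11AL): None,
    ("OR10A6 A117V/V140G/L287P", Z6_11AL): None,
    ("OR2W1 ref", Z4_9AL): (119.31, 23.09),
    ("OR2W1 ref", Z4_11AL): (65.11, 35.75),
    ("OR2W1 ref", Z6_11AL): (103.73, 27.01),
    ("OR2W1 M81V", Z4_9AL): (142.09, 92.38),
    ("OR2W1 M81V", Z4_11AL): None,
    ("OR2W1 M81V", Z6_11AL): None,
    ("OR2W1 D296N", Z4_9AL): (91.82, 46.19),
    ("OR2W1 D296N", Z4_11AL): (40.42, 11.98),
    ("OR2W1 D296N", Z6_11AL): (137.89, 54.98),
}

#: Saturating amplitude relative to the OR1A1 positive control (calibrated here).
AMPLITUDE_TABLE: dict[tuple[str, str], float] = {
    ("OR10A6 L287P", Z4_9AL): 1.0,
    ("OR10A6 L287P", Z4_11AL): 1.0,
    ("OR10A6 L287P", Z6_11AL): 1.0,
    ("OR2W1 ref", Z4_9AL): 1.0,
    ("OR2W1 ref", Z4_11AL): 0.21,
    ("OR2W1 ref", Z6_11AL): 0.21,
    ("OR2W1 M81V", Z4_9AL): 0.5,
    ("OR2W1 D296N", Z4_9AL): 0.8,
    ("OR2W1 D296N", Z4_11AL): 0.25,
    ("OR2W1 D296N", Z6_11AL): 0.2,
}

DEFAULT_HILLSLOPE = 1.0


def receptor_truth(variant_id: str, odorant: str) -> ReceptorTruth:
    """Ground-truth pharmacology for a (variant, odorant) pair.

    Non-responding pairs come back with ``responder=False``.
    """
    key = (variant_id, odorant)
    if key not in EC50_TABLE:
        raise UnknownVariantError(f"no reference entry for {variant_id} / {odorant}")
    entry = EC50_TABLE[key]
    if entry is None:
        return ReceptorTruth(variant_id=variant_id, responder=False, odorant=odorant)
    mean_ec50, _sd = entry
    return ReceptorTruth(
        variant_id=variant_id,
        responder=True,
        ec50_umol_per_L=mean_ec50,
        hillslope=DEFAULT_HILLSLOPE,
        amplitude=AMPLITUDE_TABLE[key],
        odorant=odorant,
    )


def responder_truths(odorant: str) -> list[ReceptorTruth]:
    """All reference receptors that respond to ``odorant``."""
    return [
        receptor_truth(v, o)
        for (v, o), entry in EC50_TABLE.items()
        if o == odorant and entry is not None
    ]


# IUPAC 2021 abridged standard atomic weights (g/mol).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Element composition of the odorants handled by the pipeline.
ODORANT_FORMULAS: dict[str, dict[str, int]] = {
    Z4_11AL: {"C": 11, "H": 20, "O": 1},  # (Z)-4-undecenal
    Z4_9AL: {"C": 9, "H": 16, "O": 1},  # (Z)-4-nonenal
    Z6_11AL: {"C": 11, "H": 20, "O": 1},  # (Z)-6-undecenal
    "decanal": {"C": 10, "H": 20, "O": 1},  # internal standard
    "R-carvone": {"C": 10, "H": 14, "O": 1},  # positive-control odorant
}
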