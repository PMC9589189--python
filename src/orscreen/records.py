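"""Domain records and generator configurations.

The tabular pipeline operates on :class:`pandas.DataFrame` objects whose
columns follow the plain-CSV schemas in :mod:`orscreen.io`; the dataclasses
here give those rows a typed, validated form and hold the generator
configurations (all of which serialize to/from JSON and carry a mandatory
random seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

from .errors import InvalidConfigError, MalformedRecordError

WELL_ROLES = ("test", "mock", "positive")

#: Receptor/odorant pair used as the per-plate normalization reference:
#: OR1A1 stimulated with 30 umol/L R-(-)-carvone.
POSITIVE_CONTROL_RECEPTOR = "OR1A1"
POSITIVE_CONTROL_ODORANT = "R-carvone"
POSITIVE_CONTROL_CONC_UM = 30.0


@dataclass(frozen=True)
class WellRecord:
    """One 96-well plate well: three basal and three post-stimulus reads.

    Luminescence is read three times at 60 s intervals before odorant
    application (basal) and three times after (post); the well summary is
    mean(post) - mean(basal).
    """

    plate_id: str
    well_id: str
    variant_id: str
    role: str
    odorant: str
    conc_umol_per_L: float
    basal_reads: tuple[float, float, float]
    post_reads: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise MalformedRecordError(f"unknown well role {self.role!r}")
        for name, reads in (("basal", self.basal_reads), ("post", self.post_reads)):
            if len(reads) != 3:
                raise MalformedRecordError(
                    f"well {self.well_id}: expected 3 {name} reads, got {len(reads)}"
                )
            if any(r is None or not math.isfinite(r) or r < 0 for r in reads):
                raise MalformedRecordError(
                    f"well {self.well_id}: {name} reads must be finite and >= 0"
                )
        if self.conc_umol_per_L < 0:
            raise MalformedRecordError("concentration must be >= 0")


@dataclass(frozen=True)
class ReceptorTruth:
    """Ground-truth pharmacology of one receptor variant for one odorant.

    ``amplitude`` is the saturating response as a fraction of the
    positive-control (OR1A1 / R-(-)-carvone) amplitude on the same plate.
    """

    variant_id: str
    responder: bool
    ec50_umol_per_L: float | None = None
    hillslope: float = 1.0
    amplitude: float = 0.0
    odorant: str = "Z4-11Al"

    def __post_init__(self) -> None:
        if self.responder:
            if self.ec50_umol_per_L is None or self.amplitude is None:
                raise InvalidConfigError(
                    f"{self.variant_id}: responder requires ec50 and amplitude"
                )
            if self.ec50_umol_per_L <= 0:
                raise InvalidConfigError(f"{self.variant_id}: ec50 must be > 0")
        if self.hillslope <= 0:
            raise InvalidConfigError(f"{self.variant_id}: hillslope must be > 0")
        if self.amplitude is not None and self.amplitude < 0:
            raise InvalidConfigError(f"{self.variant_id}: amplitude must be >= 0")


class _JsonConfig:
    """JSON round-trip shared by the generator configs."""

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, ReceptorTruth):
                return asdict(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=default, indent=2)

    @classmethod
    def from_json(cls, text: str):
        data = json.loads(text)
        if "planted" in data:
            data["planted"] = tuple(ReceptorTruth(**t) for t in data["planted"])
        if "trials" in data:
            data["trials"] = tuple((o, float(a)) for o, a in data["trials"])
        if "haplotype_freqs" in data and data["haplotype_freqs"] is not None:
            data["haplotype_freqs"] = {
                g: dict(f) for g, f in data["haplotype_freqs"].items()
            }
        if "detect_prob_carrier" in data and isinstance(data["detect_prob_carrier"], dict):
            data["detect_prob_carrier"] = {
                float(k): float(v) for k, v in data["detect_prob_carrier"].items()
            }
        return cls(**data)


@dataclass(frozen=True)
class ScreenConfig(_JsonConfig):
    """Configuration of one synthetic receptor-library screen.

    Defaults reproduce the study's library design: 616 OR variants (391
    wild-types plus 225 frequent haplotypes) transfected in duplicate, with a
    mock-transfected negative control and an OR1A1 + 30 umol/L R-(-)-carvone
    positive control on every 96-well plate, screened at 30 umol/L odorant.
    """

    seed: int
    n_variants: int = 616
    n_duplicates: int = 2
    basal_mean: float = 1000.0
    noise_cv: float = 0.05
    plate_scale_sd: float = 0.10
    planted: tuple[ReceptorTruth, ...] = ()
    screen_concentration_umol_per_L: float = 30.0
    odorant: str = "Z4-11Al"
    pc_delta: float = 4000.0  # positive-control delta-signal, raw LU

    def __post_init__(self) -> None:
        if self.basal_mean <= 0:
            raise InvalidConfigError("basal_mean must be > 0")
        if self.screen_concentration_umol_per_L <= 0:
            raise InvalidConfigError("screen concentration must be > 0")
        if self.noise_cv < 0 or self.plate_scale_sd < 0:
            raise InvalidConfigError("noise_cv and plate_scale_sd must be >= 0")
        if self.n_duplicates < 1 or self.n_variants < 1:
            raise InvalidConfigError("counts must be >= 1")
        if self.pc_delta <= 0:
            raise InvalidConfigError("pc_delta must be > 0")
        ids = [t.variant_id for t in self.planted]
        if len(set(ids)) != len(ids):
            raise InvalidConfigError("planted variant_ids must be unique")
        if self.n_variants < len(self.planted):
            raise InvalidConfigError("n_variants smaller than number of planted variants")


@dataclass(frozen=True)
class PanelConfig(_JsonConfig):
    """Configuration of a simulated triangle-test sensory panel.

    Panelists draw OR10A6 and OR2W1 diplotypes independently at the supplied
    population haplotype frequencies (percent). Carriers of the functional
    variant answer each trial correctly with the amount-dependent detection
    probability; everyone else performs at ``chance_prob`` (1/3 for a
    triangle test).
    """

    seed: int
    n_panelists: int = 29
    haplotype_freqs: Mapping[str, Mapping[str, float]] | None = None
    detect_prob_carrier: Mapping[float, float] | float = field(
        default_factory=lambda: {10.0: 1.0, 1.0: 0.9, 0.1: 1.0 / 3.0}
    )
    chance_prob: float = 1.0 / 3.0
    trials: tuple[tuple[str, float], ...] = (("Z4-11Al", 1.0), ("Z4-11Al", 10.0))
    functional_variant: str = "OR10A6 L287P"
    force_n_carriers: int | None = None

    def __post_init__(self) -> None:
        if not self.trials:
            raise InvalidConfigError("trials must be non-empty")
        if not 0 < self.chance_prob < 1:
            raise InvalidConfigError("chance_prob must be in (0,1)")
        probs = (
            self.detect_prob_carrier.values()
            if isinstance(self.detect_prob_carrier, Mapping)
            else [self.detect_prob_carrier]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidConfigError("detection probabilities must be in [0,1]")
        if self.haplotype_freqs is not None:
            for gene, freqs in self.haplotype_freqs.items():
                if any(f < 0 or f > 100 for f in freqs.values()):
                    raise InvalidConfigError(f"{gene}: frequencies must be in [0,100]%")
        if self.force_n_carriers is not None and not (
            0 <= self.force_n_carriers <= self.n_panelists
        ):
            raise InvalidConfigError("force_n_carriers outside [0, n_panelists]")

    def detect_prob(self, amount_ng: float) -> float:
        """Carrier detection probability for a stimulus amount (ng)."""
        if isinstance(self.detect_prob_carrier, Mapping):
            return self.detect_prob_carrier.get(float(amount_ng), self.chance_prob)
        return float(self.detect_prob_carrier)


@dataclass(frozen=True)
class HeadspacePreset(_JsonConfig):
    """Per-strain generator of GC-MS peak-area tables.

    Each batch (60 female flies sampled over 24 h, hexane rinse spiked with
    100 ng decanal) yields peak areas for Z4-9Al, Z4-11Al and the internal
    standard. The per-batch Z4-9Al/Z4-11Al ratio is lognormal:
    log-ratio ~ Normal(log_mean_ratio_9al_over_11al, log_sd_ratio). A ``None``
    log-mean encodes absent Z4-9Al (cosmopolitan strain).
    """

    seed: int
    strain: str = "zimbabwe"
    log_mean_ratio_9al_over_11al: float | None = None
    log_sd_ratio: float = 0.0
    mean_11al_ng: float = 10.0
    n_batches: int = 10
    amount_log_sd: float = 0.3  # batch-to-batch spread of total emission
    is_ng: float = 100.0  # spiked decanal, ng

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise InvalidConfigError("n_batches must be >= 1")
        if self.log_sd_ratio < 0 or self.amount_log_sd < 0:
            raise InvalidConfigError("log-scale SDs must be >= 0")
        if self.mean_11al_ng <= 0 or self.is_ng <= 0:
            raise InvalidConfigError("amounts must be > 0")
        if self.strain == "cosmopolitan" and self.log_mean_ratio_9al_over_11al is not None:
            raise InvalidConfigError("cosmopolitan preset must not emit Z4-9Al")

    # Reported Zimbabwe emission: Z4-9Al at 2.6 +/- 0.7 times Z4-11Al (n=10).
    ZIMBABWE_MEAN_RATIO = 2.6
    ZIMBABWE_SD_RATIO = 0.7

    @classmethod
    def zimbabwe(cls, seed: int, n_batches: int = 10) -> "HeadspacePreset":
        """Zimbabwe strain: lognormal ratio with arithmetic mean 2.6, SD 0.7.

        Method-of-moments calibration: sigma^2 = ln(1 + (sd/mean)^2),
        mu = ln(mean) - sigma^2/2, so the lognormal's arithmetic moments match
        the reported mean and SD.
        """
        m, s = cls.ZIMBABWE_MEAN_RATIO, cls.ZIMBABWE_SD_RATIO
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return cls(
            seed=seed,
            strain="zimbabwe",
            log_mean_ratio_9al_over_11al=mu,
            log_sd_ratio=math.sqrt(sigma2),
            n_batches=n_batches,
        )

    @classmethod
    def cosmopolitan(cls, seed: int, n_batches: int = 9) -> "HeadspacePreset":
        """Cosmopolitan strain: Z4-11Al only, no detectable Z4-9Al."""
        return cls(seed=seed, strain="cosmopolitan", n_batches=n_batches)


def wells_to_records(df) -> list[WellRecord]:
    """Convert a plate table (schema of :mod:`orscreen.io`) to WellRecords."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            WellRecord(
                plate_id=str(row.plate_id),
                well_id=str(row.well_id),
                variant_id=str(row.variant_id),
                role=str(row.role),
                odorant=str(row.odorant),
                conc_umol_per_L=float(row.conc_umolL),
                basal_reads=(float(row.basal_1), float(row.basal_2), float(row.basal_3)),
                post_reads=(float(row.post_1), float(row.post_2), float(row.post_3)),
            )
        )
    return out


def check_plate_frame(df) -> None:
    """Validate a plate table against the CSV schema; raise on malformed rows."""
    from .io import PLATE_COLUMNS  # local import to avoid a cycle

    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"plate table missing columns: {missing}")
    bad_roles = set(df["role"].unique()) - set(WELL_ROLES)
    if bad_roles:
        raise MalformedRecordError(f"unknown well roles: {sorted(bad_roles)}")
    reads = df[[c for c in df.columns if c.startswith(("basal_", "post_"))]]
    if reads.isna().any().any():
        raise MalformedRecordError("plate table contains missing luminescence reads")


__all__: Sequence[str] = [
    "WellRecord",
    "ReceptorTruth",
    "ScreenConfig",
    "PanelConfig",
    "HeadspacePreset",
    "WELL_ROLES",
    "POSITIVE_CONTROL_RECEPTOR",
    "POSITIVE_CONTROL_ODORANT",
    "POSITIVE_CONTROL_CONC_UM",
    "wells_to_records",
    "check_plate_frame",
]
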