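"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of the study's assays so the
whole analysis chain is testable without the deposited raw data:

* ``gen_screen`` — 96-well luminescence plates for a 616-variant receptor
  library in duplicate, with mock-transfected negative controls and an OR1A1
  + 30 umol/L R-(-)-carvone positive control on every plate; three basal and
  three post-stimulus reads per well.
* ``gen_dose_response`` — triplicate concentration-response plates with
  matched mock wells.
* ``gen_panel`` — triangle-test responses of panelists whose OR10A6/OR2W1
  diplotypes are drawn at the published population haplotype frequencies.
* ``gen_headspace`` — GC-MS peak-area tables with a 100 ng decanal internal
  standard.

Noise model: luminescence reads carry multiplicative Gaussian noise with a
fixed coefficient of variation (luminescence noise scales with signal), and
each plate carries a multiplicative scale factor (transfection-efficiency /
reagent batch effects) that the positive-control normalization removes.
All generators are deterministic given their config's seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genotyping
from .dose_response import hill
from .errors import InvalidConfigError
from .records import (
    POSITIVE_CONTROL_CONC_UM,
    POSITIVE_CONTROL_ODORANT,
    POSITIVE_CONTROL_RECEPTOR,
    HeadspacePreset,
    PanelConfig,
    ReceptorTruth,
    ScreenConfig,
)

_WELL_IDS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]

#: Nominal internal-standard peak area; cancels out of every quantified amount.
_IS_AREA_SCALE = 1.0e6


def _noisy_reads(rng, true_level, scale, cv, n_reads=3):
    """Multiplicative-Gaussian read triplets around true_level*scale."""
    true_level = np.asarray(true_level, dtype=float)[:, None]
    if cv > 0:
        noise = rng.normal(0.0, cv, size=(true_level.shape[0], n_reads))
    else:
        noise = np.zeros((true_level.shape[0], n_reads))
    return true_level * scale * (1.0 + noise)


def _truth_delta(truth: ReceptorTruth, conc: float, pc_delta: float) -> float:
    """Raw-LU delta-signal of a planted receptor at one concentration."""
    if not truth.responder:
        return 0.0
    return truth.amplitude * pc_delta * float(
        hill(conc, truth.ec50_umol_per_L, truth.hillslope)
    )


def gen_screen(cfg: ScreenConfig) -> pd.DataFrame:
    """Generate one receptor-library screen as a plate table.

    Variants are packed onto consecutive 96-well plates, each carrying
    ``n_duplicates`` mock wells, ``n_duplicates`` positive-control wells and
    ``n_duplicates`` wells per variant. Planted responders are elevated by
    amplitude * pc_delta * Hill(screen concentration); everything else has
    post mean equal to basal mean.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = {t.variant_id: t for t in cfg.planted}
    n_filler = cfg.n_variants - len(planted)
    ids = list(planted) + [f"ORlib{i:04d}" for i in range(1, n_filler + 1)]
    ids = [ids[i] for i in rng.permutation(len(ids))]

    capacity = (96 - 2 * cfg.n_duplicates) // cfg.n_duplicates
    if capacity < 1:
        raise InvalidConfigError("n_duplicates too large for a 96-well plate")
    chunks = [ids[i : i + capacity] for i in range(0, len(ids), capacity)]

    frames = []
    for p, chunk in enumerate(chunks, start=1):
        variants = ["mock"] * cfg.n_duplicates + [POSITIVE_CONTROL_RECEPTOR] * cfg.n_duplicates
        roles = ["mock"] * cfg.n_duplicates + ["positive"] * cfg.n_duplicates
        deltas = [0.0] * cfg.n_duplicates + [cfg.pc_delta] * cfg.n_duplicates
        for v in chunk:
            variants += [v] * cfg.n_duplicates
            roles += ["test"] * cfg.n_duplicates
            dv = _truth_delta(planted[v], cfg.screen_concentration_umol_per_L, cfg.pc_delta) if v in planted else 0.0
            deltas += [dv] * cfg.n_duplicates

        n_wells = len(variants)
        scale = 1.0 + rng.normal(0.0, cfg.plate_scale_sd) if cfg.plate_scale_sd > 0 else 1.0
        scale = max(scale, 0.05)
        basal_true = np.full(n_wells, cfg.basal_mean)
        post_true = basal_true + np.asarray(deltas)
        basal = _noisy_reads(rng, basal_true, scale, cfg.noise_cv)
        post = _noisy_reads(rng, post_true, scale, cfg.noise_cv)

        is_pos = np.array([r == "positive" for r in roles])
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": f"P{p:02d}",
                    "well_id": _WELL_IDS[:n_wells],
                    "variant_id": variants,
                    "role": roles,
                    "odorant": np.where(is_pos, POSITIVE_CONTROL_ODORANT, cfg.odorant),
                    "conc_umolL": np.where(
                        is_pos, POSITIVE_CONTROL_CONC_UM, cfg.screen_concentration_umol_per_L
                    ),
                    "basal_1": basal[:, 0],
                    "basal_2": basal[:, 1],
                    "basal_3": basal[:, 2],
                    "post_1": post[:, 0],
                    "post_2": post[:, 1],
                    "post_3": post[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_screen_config(seed: int, odorant: str = "Z4-11Al",
                          concentration: float = 30.0,
                          planted: tuple[ReceptorTruth, ...] | None = None) -> ScreenConfig:
    """The study's default screen: 616 variants, OR10A6 L287P planted.

    At 30 umol/L Z4-11Al only OR10A6 L287P responds above noise; pass other
    ``planted`` truths to emulate e.g. the 100 umol/L Z4-9Al screen where
    OR2W1 also responds.
    """
    from .reference import receptor_truth

    if planted is None:
        planted = (receptor_truth("OR10A6 L287P", odorant),)
    return ScreenConfig(
        seed=seed,
        planted=planted,
        odorant=odorant,
        screen_concentration_umol_per_L=concentration,
    )


def gen_dose_response(
    truth: ReceptorTruth,
    concentrations,
    n_transfections: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    basal_mean: float = 1000.0,
    pc_delta: float = 4000.0,
) -> pd.DataFrame:
    """Generate a concentration-response plate for one (variant, odorant).

    Per concentration: ``n_transfections`` test wells and matched mock wells;
    one positive-control triplet per plate. Test-well responses follow the
    Hill function scaled by the receptor's amplitude.
    """
    concentrations = np.asarray(list(concentrations), dtype=float)
    if concentrations.size == 0:
        raise InvalidConfigError("empty concentration list")
    if np.any(concentrations <= 0):
        raise InvalidConfigError("concentrations must be strictly positive")
    if basal_mean <= 0 or pc_delta <= 0 or n_transfections < 1:
        raise InvalidConfigError("invalid dose-response generator settings")
    rng = np.random.default_rng(seed)

    variants, roles, odorants, concs, deltas = [], [], [], [], []
    for rep in range(n_transfections):
        variants.append(POSITIVE_CONTROL_RECEPTOR)
        roles.append("positive")
        odorants.append(POSITIVE_CONTROL_ODORANT)
        concs.append(POSITIVE_CONTROL_CONC_UM)
        deltas.append(pc_delta)
    for c in concentrations:
        for rep in range(n_transfections):
            variants += [truth.variant_id, "mock"]
            roles += ["test", "mock"]
            odorants += [truth.odorant, truth.odorant]
            concs += [c, c]
            deltas += [_truth_delta(truth, c, pc_delta), 0.0]

    n_wells = len(variants)
    basal_true = np.full(n_wells, basal_mean)
    post_true = basal_true + np.asarray(deltas)
    basal = _noisy_reads(rng, basal_true, 1.0, noise_cv)
    post = _noisy_reads(rng, post_true, 1.0, noise_cv)
    return pd.DataFrame(
        {
            "plate_id": "DR01",
            "well_id": [f"W{i:03d}" for i in range(1, n_wells + 1)],
            "variant_id": variants,
            "role": roles,
            "odorant": odorants,
            "conc_umolL": concs,
            "basal_1": basal[:, 0],
            "basal_2": basal[:, 1],
            "basal_3": basal[:, 2],
            "post_1": post[:, 0],
            "post_2": post[:, 1],
            "post_3": post[:, 2],
        }
    )


def gen_panel(cfg: PanelConfig) -> pd.DataFrame:
    """Simulate triangle-test responses conditioned on simulated diplotypes.

    OR10A6 and OR2W1 diplotypes are drawn independently at the population
    haplotype frequencies (linkage between the genes is not modelled).
    Carriers of a *functional* haplotype bearing the variant answer each
    trial correctly with the amount-dependent detection probability;
    everyone else — including carriers of non-functional haplotypes that
    happen to contain the same site, like the OR10A6 triple mutant — at
    chance. ``force_n_carriers`` pins the carrier count (the first k
    panelists carry the functional haplotype, the rest are guaranteed
    non-carriers) for worked expectation checks.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_f, label_f = cfg.functional_variant.split(" ", 1)
    freqs = cfg.haplotype_freqs or {
        g: genotyping.haplotype_frequencies(g) for g in ("OR10A6", "OR2W1")
    }
    carriers_of = genotyping.carrier_labels(
        gene_f, cfg.functional_variant, functional_only=True
    )

    def draw(gene: str, size, labels_subset=None):
        table = freqs[gene]
        labels = [l for l in table if table[l] > 0]
        if labels_subset is not None:
            labels = [l for l in labels if l in labels_subset]
        p = np.array([table[l] for l in labels], dtype=float)
        if not labels or p.sum() <= 0:
            raise InvalidConfigError(f"{gene}: no haplotypes with positive frequency")
        # object dtype: fixed-width numpy strings would truncate long labels
        return rng.choice(np.array(labels, dtype=object), size=size, p=p / p.sum())

    n = cfg.n_panelists
    dips: dict[str, np.ndarray] = {}
    for gene in freqs:
        haps = draw(gene, (n, 2))
        if gene == gene_f and cfg.force_n_carriers is not None:
            k = cfg.force_n_carriers
            non_carrier = frozenset(freqs[gene]) - carriers_of
            haps[:k, 0] = label_f
            haps[k:, 0] = draw(gene, (n - k,), non_carrier)
            haps[k:, 1] = draw(gene, (n - k,), non_carrier)
        dips[gene] = haps

    f_haps = dips[gene_f]
    carrier = np.array(
        [h1 in carriers_of or h2 in carriers_of for h1, h2 in f_haps]
    )

    rows = []
    for j, (odorant, amount) in enumerate(cfg.trials, start=1):
        p_correct = np.where(carrier, cfg.detect_prob(amount), cfg.chance_prob)
        correct = (rng.random(n) < p_correct).astype(int)
        for i in range(n):
            rows.append(
                {
                    "panelist_id": f"S{i + 1:02d}",
                    "or10a6_diplotype": "|".join(dips["OR10A6"][i]),
                    "or2w1_diplotype": "|".join(dips["OR2W1"][i]),
                    "trial_id": f"T{j:02d}",
                    "odorant": odorant,
                    "amount_ng": amount,
                    "correct": correct[i],
                }
            )
    return pd.DataFrame(rows)


def gen_headspace(preset: HeadspacePreset) -> pd.DataFrame:
    """Generate a per-batch GC-MS peak-area table for one fly strain.

    Each batch's Z4-11Al amount is lognormal around ``mean_11al_ng``; the
    Z4-9Al/Z4-11Al ratio is lognormal per the preset (zero when the preset's
    log-mean is ``None``, as for cosmopolitan flies). Peak areas are amounts
    expressed on the internal-standard area scale, so the spiked 100 ng of
    decanal anchors quantification.
    """
    rng = np.random.default_rng(preset.seed)
    n = preset.n_batches
    amount_mu = np.log(preset.mean_11al_ng) - preset.amount_log_sd**2 / 2.0
    ng_11 = np.exp(rng.normal(amount_mu, preset.amount_log_sd, size=n))
    if preset.log_mean_ratio_9al_over_11al is None:
        ratio = np.zeros(n)
    else:
        ratio = np.exp(
            rng.normal(preset.log_mean_ratio_9al_over_11al, preset.log_sd_ratio, size=n)
        )
    ng_9 = ratio * ng_11
    area_is = _IS_AREA_SCALE * np.exp(rng.normal(0.0, 0.05, size=n))
    return pd.DataFrame(
        {
            "sample_id": [f"{preset.strain[:3]}{i:02d}" for i in range(1, n + 1)],
            "strain": preset.strain,
            "area_z4_9al": ng_9 / preset.is_ng * area_is,
            "area_z4_11al": ng_11 / preset.is_ng * area_is,
            "area_is": area_is,
            "is_ng": preset.is_ng,
        }
    )
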