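"""Seeded generators for every pipeline input.

The study's raw inputs — odor-port beam-break streams, operant trial tables,
glomerular section images, spike trains, and per-region cell counts — are
emulated here with the statistical structure the downstream analyses assume,
so every stage can be tested without animal data.  Every generated object
carries its ground-truth parameters in a ``truth`` attribute so estimators can
be scored for recovery, and a fixed seed reproduces output bit-identically.

Behavioral model.  Investigation is a bout process: within each scheduled
epoch, bout onsets form a homogeneous Poisson process and bout durations are
exponential.  The air-epoch bout rate decays geometrically (per-trial
habituation) as the animal habituates to the chamber; odor epochs modulate the
habituated air baseline by valence:

* attractive — novelty and attraction both drive investigation, so rate and
  bout duration are boosted for the first two presentations;
* neutral — a transient novelty boost on the first presentation only;
* aversive — the first presentation matches the air baseline (risk assessment
  offsets avoidance) and later presentations are suppressed, since novelty
  habituates quickly while avoidance persists.

Defaults (2 bouts/min habituated baseline, 1.5 s mean bout, novelty gain 3,
habituation constant 0.85, aversive suppression 0.3) produce rasters in the
regime of real odor-port sessions: sparse sub-to-few-second investigation
bouts that wane over air trials and rebound on odor onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activation import REGION_SECTIONS, RegionCounts
from .behavior import (
    EpochSchedule,
    EventStream,
    SpikeTrain,
    preference_schedule,
)
from .imaging import GlomerulusImage
from .psychometrics import PsychometricModel, weibull_sr

__all__ = [
    "GeneratorConfig",
    "gen_investigation_session",
    "gen_psychometric_trials",
    "gen_choice_trials",
    "gen_glomerulus_image",
    "gen_spike_train",
    "gen_region_cells",
    "gen_dishabituation_scan_table",
]

VALENCE_CLASSES = ("attractive", "neutral", "aversive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic investigation-session generator.

    Rates are bouts/min, durations seconds; ``habituation_constant`` and
    ``aversion_suppression`` are multiplicative factors in (0, 1].
    """

    seed: int = 0
    schedule: EpochSchedule = field(default_factory=preference_schedule)
    valence_class: str = "neutral"
    base_bout_rate: float = 2.0
    bout_duration_mean: float = 1.5
    novelty_gain: float = 3.0
    habituation_constant: float = 0.85
    aversion_suppression: float = 0.3

    def __post_init__(self) -> None:
        if self.valence_class not in VALENCE_CLASSES:
            raise ValueError(f"valence_class must be one of {VALENCE_CLASSES}")
        if not (self.base_bout_rate > 0 and self.bout_duration_mean > 0):
            raise ValueError("rates and durations must be strictly positive")
        if not self.novelty_gain > 0:
            raise ValueError("novelty_gain must be strictly positive")
        if not 0 < self.habituation_constant <= 1:
            raise ValueError("habituation_constant must be in (0, 1]")
        if not 0 < self.aversion_suppression <= 1:
            raise ValueError("aversion_suppression must be in (0, 1]")


def _epoch_rate_plan(config: GeneratorConfig) -> list[tuple[float, float]]:
    """(bout rate per min, mean bout duration s) for each scheduled epoch."""
    plan = []
    air_count = 0
    baseline = config.base_bout_rate
    presentations: dict[str, int] = {}
    for ep in config.schedule:
        if ep.kind == "air":
            rate = config.base_bout_rate * config.habituation_constant ** air_count
            air_count += 1
            baseline = rate
            plan.append((rate, config.bout_duration_mean))
            continue
        j = presentations.get(ep.odor_id, 0)
        presentations[ep.odor_id] = j + 1
        rate, dur = baseline, config.bout_duration_mean
        if config.valence_class == "attractive":
            if j < 2:
                rate *= config.novelty_gain
                dur *= config.novelty_gain
        elif config.valence_class == "neutral":
            if j == 0:
                rate *= config.novelty_gain
        else:  # aversive: risk assessment first, then avoidance dominates
            if j >= 1:
                rate *= config.aversion_suppression
        plan.append((rate, dur))
    return plan


def gen_investigation_session(config: GeneratorConfig,
                              subject_id: str = "subject",
                              session_id: str = "session") -> EventStream:
    """Simulate one odor-port session as a beam-break event stream.

    Bouts are drawn per epoch (Poisson onsets, exponential durations, clipped
    at the epoch end and merged when overlapping); the inter-epoch gaps carry
    no events.  The returned stream's ``truth`` holds the per-epoch rate plan
    and the analytic expected investigation time
    ``rate/60 · epoch_length · mean_bout`` (exact up to end-clipping and
    bout-merging, both negligible at the default sparse rates).
    """
    rng = np.random.default_rng(config.seed)
    plan = _epoch_rate_plan(config)
    intervals: list[tuple[float, float]] = []
    expected_t = []
    for ep, (rate, dur_mean) in zip(config.schedule, plan):
        length = ep.duration_s
        n = rng.poisson(rate / 60.0 * length)
        onsets = np.sort(rng.uniform(ep.start_s, ep.end_s, size=n))
        durs = rng.exponential(dur_mean, size=n)
        merged: list[list[float]] = []
        for on, d in zip(onsets, durs):
            off = min(on + d, ep.end_s)
            if off <= on:
                continue
            if merged and on <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], off)
            else:
                merged.append([on, off])
        intervals.extend((a, b) for a, b in merged)
        expected_t.append(rate / 60.0 * length * dur_mean)
    truth = {
        "valence_class": config.valence_class,
        "epoch_rate_per_min": [r for r, _ in plan],
        "epoch_bout_mean_s": [d for _, d in plan],
        "expected_t_s": expected_t,
        "config": config,
    }
    return EventStream(intervals=np.array(intervals, dtype=float).reshape(-1, 2),
                       subject_id=subject_id, session_id=session_id, truth=truth)


def gen_psychometric_trials(truth: PsychometricModel, concentrations,
                            n_subjects: int, noise_sd: float, seed: int,
                            variant: str = "continuous",
                            n_trials_per_conc: int = 20) -> pd.DataFrame:
    """Concentration–response tables from a known psychometric curve.

    ``continuous`` draws per-subject responses as the Weibull mean plus
    Gaussian noise (the ΔNPI dishabituation readout); ``binary`` draws
    per-subject Bernoulli successes with p = SR(x)/100 (the Go/No-Go readout),
    reporting ``n_success``/``n_trials`` and the percent response.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing and positive")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    mean = weibull_sr(conc, truth)
    rows = []
    for s in range(n_subjects):
        for x, m in zip(conc, mean):
            if variant == "continuous":
                rows.append({"subject_id": f"s{s}", "concentration": x,
                             "response": m + rng.normal(0.0, noise_sd) if noise_sd else m})
            elif variant == "binary":
                k = rng.binomial(n_trials_per_conc, np.clip(m / 100.0, 0.0, 1.0))
                rows.append({"subject_id": f"s{s}", "concentration": x,
                             "n_trials": n_trials_per_conc, "n_success": int(k),
                             "response": 100.0 * k / n_trials_per_conc})
            else:
                raise ValueError(f"unknown variant {variant!r}")
    return pd.DataFrame(rows)


def gen_choice_trials(policy: str, task: str, n_trials: int, seed: int,
                      bias_p: float = 0.5) -> pd.DataFrame:
    """Trial tables for the two-choice and Go/No-Go tasks.

    The stimulus sequence is balanced and pseudo-random (equal counts,
    shuffled).  Policies: ``oracle`` always acts correctly, ``random`` picks an
    action uniformly, ``biased`` licks (Go/No-Go) or pokes port A (two-choice)
    with probability ``bias_p`` regardless of the stimulus.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if task == "two_choice":
        stimuli, actions = ("A", "B"), ("portA", "portB")
        correct_action = {"A": "portA", "B": "portB"}
    elif task == "go_nogo":
        stimuli, actions = ("CS+", "CS-"), ("lick", "no-lick")
        correct_action = {"CS+": "lick", "CS-": "no-lick"}
    else:
        raise ValueError(f"unknown task {task!r}")
    if policy not in ("oracle", "random", "biased"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(seed)
    seq = np.array([stimuli[i % 2] for i in range(n_trials)])
    rng.shuffle(seq)
    rows = []
    for i, stim in enumerate(seq):
        if policy == "oracle":
            act = correct_action[stim]
        elif policy == "random":
            act = actions[rng.integers(2)]
        else:
            act = actions[0] if rng.random() < bias_p else actions[1]
        rows.append({"trial_index": i, "stimulus": stim, "action": act,
                     "correct": act == correct_action[stim]})
    return pd.DataFrame(rows)


def _grow_compartment(rng: np.random.Generator, roi: np.ndarray,
                      taken: np.ndarray, target: int) -> None:
    """Random-walk region growth of a contiguous blob of ``target`` pixels
    inside ``roi``, marked into ``taken`` in place."""
    free_r, free_c = np.nonzero(roi & ~taken)
    if len(free_r) == 0 or target <= 0:
        return
    start = rng.integers(len(free_r))
    frontier = [(int(free_r[start]), int(free_c[start]))]
    in_frontier = {frontier[0]}
    grown = 0
    h, w = roi.shape
    while frontier and grown < target:
        k = rng.integers(len(frontier))
        r, c = frontier.pop(k)
        in_frontier.discard((r, c))
        if taken[r, c]:
            continue
        taken[r, c] = True
        grown += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and roi[nr, nc] and not taken[nr, nc] \
                    and (nr, nc) not in in_frontier:
                frontier.append((nr, nc))
                in_frontier.add((nr, nc))


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def gen_glomerulus_image(roi_diameter_px: int, occupied_fraction: float,
                         n_compartments: int = 1,
                         channel_set=("axon", "dendrite", "marker", "nuclei"),
                         seed: int = 0, pixel_size_um: float = 1.0,
                         n_glomeruli: int = 1, margin_px: int = 6) -> GlomerulusImage:
    """Synthetic glomerular section image.

    Each glomerulus is a circular ROI; the marker channel (OMP/NCAM-like)
    fills the ROI, the dendrite channel fills it uniformly, and the axon
    channel fills ``n_compartments`` contiguous random-growth compartments
    totalling ``occupied_fraction`` of the ROI area (exact to pixel
    quantization) — the compartmentalized-innervation phenotype; fraction 1
    reproduces the fully innervated wild-type pattern.  ``n_glomeruli`` > 1
    lays out disjoint glomeruli on a jittered grid for counting tests.
    """
    if roi_diameter_px < 8:
        raise ValueError("roi_diameter_px must be at least 8")
    if not 0.0 <= occupied_fraction <= 1.0:
        raise ValueError("occupied_fraction must be in [0, 1]")
    if n_compartments < 1 or n_glomeruli < 1:
        raise ValueError("n_compartments and n_glomeruli must be >= 1")
    rng = np.random.default_rng(seed)
    radius = roi_diameter_px / 2.0
    cell = roi_diameter_px + 2 * margin_px
    n_cols = int(np.ceil(np.sqrt(n_glomeruli)))
    n_rows = int(np.ceil(n_glomeruli / n_cols))
    shape = (n_rows * cell, n_cols * cell)
    rois: list[np.ndarray] = []
    for g in range(n_glomeruli):
        gr, gc = divmod(g, n_cols)
        jitter = rng.uniform(-margin_px / 2, margin_px / 2, size=2)
        center = (gr * cell + cell / 2 + jitter[0], gc * cell + cell / 2 + jitter[1])
        rois.append(_disc(shape, center, radius))
    marker = np.zeros(shape, dtype=float)
    dendrite = np.zeros(shape, dtype=float)
    axon_mask = np.zeros(shape, dtype=bool)
    for roi in rois:
        marker[roi] = 255.0
        dendrite[roi] = 200.0
        area = int(roi.sum())
        target = int(round(occupied_fraction * area))
        taken = np.zeros(shape, dtype=bool)
        per = [target // n_compartments] * n_compartments
        for i in range(target % n_compartments):
            per[i] += 1
        for t in per:
            _grow_compartment(rng, roi, taken, t)
        axon_mask |= taken
    axon = np.where(axon_mask, 255.0, 0.0)
    # periglomerular nuclei: scattered dots in the non-glomerular neuropil
    nuclei = np.zeros(shape, dtype=float)
    any_roi = np.logical_or.reduce(rois) if rois else np.zeros(shape, bool)
    n_nuclei = max(20, shape[0] * shape[1] // 200)
    pts = rng.integers(0, [shape[0], shape[1]], size=(n_nuclei, 2))
    for r, c in pts:
        if not any_roi[r, c]:
            nuclei[r, c] = 255.0
    channels = {"axon": axon, "dendrite": dendrite, "marker": marker, "nuclei": nuclei}
    truth = {
        "occupied_fraction": occupied_fraction,
        "axon_pixels": int(axon_mask.sum()),
        "roi_areas_px": [int(r.sum()) for r in rois],
        "n_compartments": n_compartments,
        "n_glomeruli": n_glomeruli,
    }
    return GlomerulusImage(channels={k: channels[k] for k in channel_set},
                           pixel_size_um=pixel_size_um, rois=rois, truth=truth)


def gen_spike_train(duration_s: float, isi_lognormal: tuple[float, float],
                    seed: int = 0) -> SpikeTrain:
    """Spike train with i.i.d. lognormal inter-spike intervals.

    ``isi_lognormal = (mu, sigma)`` parameterizes log ISI ~ Normal(mu, sigma)
    with ISI in seconds; sigma = 0 degenerates to a perfectly regular train
    with ISI = exp(mu).
    """
    mu, sigma = isi_lognormal
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    times: list[float] = []
    t = 0.0
    mean_isi = float(np.exp(mu + 0.5 * sigma ** 2))
    chunk = max(16, int(duration_s / mean_isi * 1.2) + 1)
    while t <= duration_s:
        isis = np.exp(rng.normal(mu, sigma, size=chunk)) if sigma > 0 \
            else np.full(chunk, np.exp(mu))
        for isi in isis:
            t += float(isi)
            if t > duration_s:
                break
            times.append(t)
        else:
            continue
        break
    return SpikeTrain(times_s=np.asarray(times), duration_s=float(duration_s),
                      truth={"mu": mu, "sigma": sigma})


def gen_region_cells(region_densities: dict[str, float],
                     section_areas_mm2=None, seed: int = 0,
                     hemispheres=("L", "R")) -> RegionCounts:
    """Per-section pS6+ counts: count ~ Poisson(density · area) per section and
    hemisphere.  ``section_areas_mm2`` applies to every region (default: the
    configured per-region section count at 0.5 mm² each); bregma positions are
    spaced through each region's configured range.
    """
    for region, d in region_densities.items():
        if d < 0:
            raise ValueError(f"density for {region} must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for region, density in region_densities.items():
        n_default, (b_lo, b_hi) = REGION_SECTIONS.get(region, (4, (-1.0, -0.8)))
        areas = list(section_areas_mm2) if section_areas_mm2 is not None \
            else [0.5] * n_default
        if any(a <= 0 for a in areas):
            raise ValueError("section areas must be positive")
        bregmas = np.linspace(b_lo, b_hi, len(areas))
        for hemi in hemispheres:
            for bregma, area in zip(bregmas, areas):
                rows.append({"region": region, "hemisphere": hemi,
                             "bregma_mm": float(bregma),
                             "count": int(rng.poisson(density * area)),
                             "area_mm2": float(area)})
    return RegionCounts(sections=pd.DataFrame(rows), truth=dict(region_densities))


def gen_dishabituation_scan_table(concentrations, n_subjects: int, seed: int,
                                  effect_at: float | None = None,
                                  effect_size: float = 0.0,
                                  npi_noise_sd: float = 0.25) -> pd.DataFrame:
    """Tidy NPI table for the detection-threshold scan.

    Under the null (``effect_at`` None or ``effect_size`` 0) odor and
    flanking-air NPIs are i.i.d. around 1, so every per-concentration paired
    test is a true null.  With an effect, concentrations ≥ ``effect_at`` add
    ``effect_size`` to the odor NPI — a step response for threshold-detection
    power checks.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for x in conc:
            bump = effect_size if (effect_at is not None and x >= effect_at) else 0.0
            rows.append({
                "subject_id": f"s{s}", "concentration": float(x),
                "npi_odor": max(0.0, 1.0 + bump + rng.normal(0.0, npi_noise_sd)),
                "npi_air": max(0.0, 1.0 + rng.normal(0.0, npi_noise_sd)),
            })
    return pd.DataFrame(rows)
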