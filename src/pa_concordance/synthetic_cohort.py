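"""Synthetic family cohort generator.

Emulates the data-generating process the analysis assumes: a cohort of
adults and children, each with stable latent traits (habitual weekly MPA/VPA
volume, bout-length distribution, reporting biases, wear propensity),
measured over two independent weeks (T0, T1):

* **device side** — activity happens in bouts. Bout lengths are
  gamma-distributed; children's bouts are much shorter (intermittent play)
  than adults' (walks, sessions). Bouts are rasterized into a 1-s (or 2/5/10-s)
  MET series with low-level rest noise, contiguous morning/evening non-wear
  blocks, and occasional low-wear (invalid) days.
* **diary** — participants log only bouts longer than 10 min, omit a fraction
  of them, misperceive intensity through a row-stochastic confusion matrix,
  and apply a personal (typically < 1) duration bias: under-reporting.
* **IPAQ** — weekly volume inflated by a population over-report factor and a
  personal bias, then recalled as days x minutes/day on a rounding grid:
  over-reporting.

Randomness is split into two documented substreams per participant derived
from the root seed: a *structure* stream (wear schedule, bout lengths,
MET levels, day placement, rest noise) that does not depend on the week, and
a *week* stream (volume noise, diary omission/confusion, IPAQ rounding).
Consequently, when ``week_noise_sd = 0`` and the self-report noise is turned
off, the two weeks are identical by construction — the limit in which every
downstream reliability and stability correlation must be exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .accelerometry import (
    MetSeries,
    SECONDS_PER_DAY,
    WeeklyEstimate,
    acc_weekly_estimates,
)
from .errors import ConfigurationError, ValidationError
from .self_report import DiaryEntry, IpaqResponse, score_diary, score_ipaq

WEEKS = ("T0", "T1")
WEEK_INDEX = {"T0": 0, "T1": 1}
#: measurement-week start dates (Mondays, four weeks apart)
WEEK_STARTS = {"T0": pd.Timestamp("2024-03-04"), "T1": pd.Timestamp("2024-04-01")}

#: population-level habitual volume means, min/week (MPA, VPA)
POPULATION_VOLUME_MEANS = {"adult": (300.0, 60.0), "child": (350.0, 120.0)}
#: gamma bout-length parameters (shape, scale s): adult mean 480 s, child 90 s
POPULATION_BOUT_GAMMA = {"adult": (2.0, 240.0), "child": (2.0, 45.0)}

#: MET levels assigned to bouts. Moderate activity is dominated by walking-
#: grade intensities (lower half of the 3.0-5.9 band), vigorous by running-
#: grade ones; both ranges keep clear of the (5.9, 6.0) cut-point gap.
MPA_MET_RANGE = (3.1, 4.5)
VPA_MET_RANGE = (6.1, 8.5)

#: substream tags appended to (seed, participant index)
_STRUCT_KEY = 101  # week-independent structure
_WEEK_KEY = 202  # per-week noise

_DEFAULT_CONFUSION = (
    (0.85, 0.15, 0.00),
    (0.10, 0.80, 0.10),
    (0.00, 0.15, 0.85),
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters; defaults mirror the study design
    (32 adults + 32 children, two 7-day weeks, 1-s base epochs)."""

    n_adults: int = 32
    n_children: int = 32
    base_epoch_s: int = 1
    days_per_week: int = 7
    wear_hours_mean: float = 14.0
    wear_hours_sd: float = 1.5
    p_invalid_day: float = 0.1
    trait_sd_mpa: float = 150.0
    trait_sd_vpa: float = 50.0
    week_noise_sd: float = 40.0
    diary_omission_prob: float = 0.2
    diary_intensity_confusion: tuple = _DEFAULT_CONFUSION
    ipaq_overreport_factor: float = 1.6
    ipaq_rounding_grid_min: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_adults", "n_children"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.base_epoch_s not in (1, 2, 5, 10):
            raise ConfigurationError(
                f"base_epoch_s must be one of 1, 2, 5, 10 (it must divide both 10 and 60), got {self.base_epoch_s}"
            )
        if self.days_per_week != 7:
            raise ConfigurationError(f"days_per_week must be 7, got {self.days_per_week}")
        for name in ("p_invalid_day", "diary_omission_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("wear_hours_sd", "trait_sd_mpa", "trait_sd_vpa", "week_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.wear_hours_mean <= 0:
            raise ConfigurationError("wear_hours_mean must be positive")
        if self.ipaq_overreport_factor < 1.0:
            raise ConfigurationError(
                f"ipaq_overreport_factor must be >= 1, got {self.ipaq_overreport_factor}"
            )
        if self.ipaq_rounding_grid_min <= 0:
            raise ConfigurationError("ipaq_rounding_grid_min must be positive")
        m = np.asarray(self.diary_intensity_confusion, dtype=float)
        if m.shape != (3, 3) or np.any(m < 0) or np.any(m > 1):
            raise ConfigurationError(
                "diary_intensity_confusion must be a 3x3 matrix of probabilities"
            )
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("diary_intensity_confusion rows must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        if "diary_intensity_confusion" in d:
            d = dict(d)
            d["diary_intensity_confusion"] = tuple(
                tuple(float(x) for x in row) for row in d["diary_intensity_confusion"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class ParticipantTraits:
    """Latent per-person parameters, stable across both measurement weeks."""

    participant_id: str
    population: str  # adult | child
    habitual_mpa: float  # min/week
    habitual_vpa: float
    bout_duration_shape: float
    bout_duration_scale: float  # seconds
    diary_bias: float
    ipaq_bias: float
    wear_propensity: float  # hours/day
    walk_fraction: float  # share of reported IPAQ MPA recalled as walking
    seed_index: int = 0

    def __post_init__(self) -> None:
        if self.habitual_mpa < 0 or self.habitual_vpa < 0:
            raise ValidationError("habitual volumes must be >= 0")
        if self.bout_duration_shape <= 0 or self.bout_duration_scale <= 0:
            raise ValidationError("bout duration parameters must be strictly positive")


@dataclass
class TrueActivityWeek:
    """Ground-truth bout structure for one participant-week.

    ``bouts`` holds (day index, start second within day, duration s, MET);
    ``true_mpa_min``/``true_vpa_min`` are the exact minute totals of bouts in
    the matching MET band.
    """

    participant_id: str
    week: str
    bouts: list[tuple[int, int, int, float]]
    true_mpa_min: float
    true_vpa_min: float


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _participant_rng(config: SimConfig, seed_index: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, seed_index, *tags]))


def generate_cohort(config: SimConfig) -> list[ParticipantTraits]:
    """Draw stable traits for ``n_adults + n_children`` participants.

    Deterministic given ``config.seed``: every participant's draws come from
    a dedicated substream keyed by (seed, participant index).
    """
    traits: list[ParticipantTraits] = []
    plan = [("adult", i, f"A{i:03d}") for i in range(config.n_adults)] + [
        ("child", i, f"C{i:03d}") for i in range(config.n_children)
    ]
    for seed_index, (population, _, pid) in enumerate(plan):
        rng = _participant_rng(config, seed_index)
        mpa_mean, vpa_mean = POPULATION_VOLUME_MEANS[population]
        shape, scale = POPULATION_BOUT_GAMMA[population]
        traits.append(
            ParticipantTraits(
                participant_id=pid,
                population=population,
                habitual_mpa=max(0.0, rng.normal(mpa_mean, config.trait_sd_mpa)),
                habitual_vpa=max(0.0, rng.normal(vpa_mean, config.trait_sd_vpa)),
                bout_duration_shape=shape,
                bout_duration_scale=scale * rng.lognormal(0.0, 0.25),
                diary_bias=rng.lognormal(np.log(0.9), 0.2),
                ipaq_bias=rng.lognormal(0.0, 0.35),
                wear_propensity=float(
                    np.clip(rng.normal(config.wear_hours_mean, config.wear_hours_sd), 9.0, 16.0)
                ),
                walk_fraction=rng.uniform(0.2, 0.5),
                seed_index=seed_index,
            )
        )
    return traits


# ---------------------------------------------------------------------------
# one measurement week
# ---------------------------------------------------------------------------

def _draw_bout_durations(
    rng: np.random.Generator, target_s: int, shape: float, scale: float, base: int
) -> list[int]:
    """Gamma bout lengths on the base-epoch grid summing exactly to target_s."""
    durations: list[int] = []
    total = 0
    while total < target_s:
        d = int(round(rng.gamma(shape, scale) / base)) * base
        d = min(max(d, base), 7200)
        if total + d > target_s:
            d = target_s - total
        if d > 0:
            durations.append(d)
            total += d
    return durations


def simulate_week(
    traits: ParticipantTraits, week: str, config: SimConfig
) -> tuple[TrueActivityWeek, MetSeries]:
    """Simulate one participant-week: ground truth bouts + the MET series.

    Weekly volumes are ``max(0, habitual + N(0, week_noise_sd))``. MPA bouts
    carry MET in ``MPA_MET_RANGE``, VPA in ``VPA_MET_RANGE``; rest epochs sit well below
    3 MET and non-wear epochs are flat 1.0 MET. Non-wear is placed as
    contiguous morning/evening blocks on 60-s boundaries (plus low-wear
    "invalid" days), so wear flags are homogeneous within every 10-s and
    60-s analysis epoch.
    """
    if week not in WEEK_INDEX:
        raise ValidationError(f"week must be one of {WEEKS}, got {week!r}")
    base = config.base_epoch_s
    epd = SECONDS_PER_DAY // base  # epochs per day
    n_epochs = 7 * epd

    # Structure substreams are week-independent: a person's wear routine and
    # bout repertoire (durations, intensities, preferred days) are habitual.
    # Each week consumes the prefix of the repertoire needed to reach that
    # week's volume target, so two weeks with equal targets are identical and
    # nearby targets share almost all of their bouts.
    wear_rng = _participant_rng(config, traits.seed_index, _STRUCT_KEY, 0)
    rest_rng = _participant_rng(config, traits.seed_index, _STRUCT_KEY, 1)
    place_rng = _participant_rng(config, traits.seed_index, _STRUCT_KEY, 5)
    weekly = _participant_rng(config, traits.seed_index, _WEEK_KEY, WEEK_INDEX[week])

    # --- wear schedule ------------------------------------------------------
    wear_start_ep = np.empty(7, dtype=int)
    wear_len_ep = np.empty(7, dtype=int)
    for d in range(7):
        invalid = wear_rng.random() < config.p_invalid_day
        if invalid:
            hours = wear_rng.uniform(1.0, 7.5)
        else:
            hours = float(np.clip(wear_rng.normal(traits.wear_propensity, 0.75), 8.5, 16.0))
        wear_s = int(round(hours * 3600 / 60.0)) * 60  # 60-s grid
        start_s = int(round((SECONDS_PER_DAY - wear_s) * wear_rng.uniform(0.3, 0.7) / 60.0)) * 60
        wear_start_ep[d] = start_s // base
        wear_len_ep[d] = wear_s // base

    # --- rest noise ---------------------------------------------------------
    met = np.clip(1.3 + 0.3 * rest_rng.standard_normal(n_epochs), 0.3, 2.5)
    wear = np.zeros(n_epochs, dtype=bool)
    for d in range(7):
        lo = d * epd + wear_start_ep[d]
        wear[lo : lo + wear_len_ep[d]] = True
    met[~wear] = 1.0

    # --- weekly volume targets (week stream) --------------------------------
    mpa_min = max(0.0, traits.habitual_mpa + weekly.normal(0.0, config.week_noise_sd)) if config.week_noise_sd > 0 else traits.habitual_mpa
    vpa_min = max(0.0, traits.habitual_vpa + weekly.normal(0.0, config.week_noise_sd)) if config.week_noise_sd > 0 else traits.habitual_vpa
    mpa_target_s = int(round(mpa_min * 60.0 / base)) * base
    vpa_target_s = int(round(vpa_min * 60.0 / base)) * base

    # --- bouts ---------------------------------------------------------------
    shape, scale = traits.bout_duration_shape, traits.bout_duration_scale
    bout_specs: list[tuple[int, float, int]] = []  # (duration s, MET, day)
    for tag, (target_s, (met_lo, met_hi)) in enumerate(
        (
            (mpa_target_s, MPA_MET_RANGE),
            (vpa_target_s, VPA_MET_RANGE),
        )
    ):
        dur_rng = _participant_rng(config, traits.seed_index, _STRUCT_KEY, 2, tag)
        lvl_rng = _participant_rng(config, traits.seed_index, _STRUCT_KEY, 3, tag)
        day_rng = _participant_rng(config, traits.seed_index, _STRUCT_KEY, 4, tag)
        durations = _draw_bout_durations(dur_rng, target_s, shape, scale, base)
        levels = lvl_rng.uniform(met_lo, met_hi, size=len(durations))
        days = day_rng.integers(0, 7, size=len(durations))
        bout_specs.extend(
            (dur, float(lvl), int(day)) for dur, lvl, day in zip(durations, levels, days)
        )

    # --- resolve day capacity overflow ---------------------------------------
    loads = np.zeros(7, dtype=int)
    by_day: list[list[tuple[int, float]]] = [[] for _ in range(7)]
    dropped_s = {"mpa": 0, "vpa": 0}
    cap = wear_len_ep * base
    for dur, level, day in bout_specs:
        if loads[day] + dur <= cap[day]:
            by_day[day].append((dur, level))
            loads[day] += dur
        else:
            free = cap - loads
            alt = int(np.argmax(free))
            if free[alt] >= dur:
                by_day[alt].append((dur, level))
                loads[alt] += dur
            else:  # nowhere fits: drop and shrink the true volume
                dropped_s["vpa" if level >= 6.0 else "mpa"] += dur

    # --- place bouts within each day's wear window (structure stream) --------
    bouts: list[tuple[int, int, int, float]] = []
    for d in range(7):
        day_bouts = by_day[d]
        if not day_bouts:
            continue
        order = place_rng.permutation(len(day_bouts))
        day_bouts = [day_bouts[i] for i in order]
        free_ep = wear_len_ep[d] - loads[d] // base
        k = len(day_bouts)
        gaps = place_rng.multinomial(free_ep, np.full(k + 1, 1.0 / (k + 1)))
        cursor = wear_start_ep[d]
        for (dur, level), gap in zip(day_bouts, gaps[:-1]):
            cursor += int(gap)
            dur_ep = dur // base
            lo = d * epd + cursor
            met[lo : lo + dur_ep] = level
            bouts.append((d, cursor * base, dur, level))  # start second within day
            cursor += dur_ep

    true_mpa = (mpa_target_s - dropped_s["mpa"]) / 60.0
    true_vpa = (vpa_target_s - dropped_s["vpa"]) / 60.0
    truth = TrueActivityWeek(
        participant_id=traits.participant_id,
        week=week,
        bouts=sorted(bouts),
        true_mpa_min=true_mpa,
        true_vpa_min=true_vpa,
    )
    series = MetSeries(
        participant_id=traits.participant_id,
        week=week,
        epoch_s=base,
        start=WEEK_STARTS[week],
        met=met,
        wear=wear,
    )
    return truth, series


# ---------------------------------------------------------------------------
# self-report simulation
# ---------------------------------------------------------------------------

def _bout_intensity(level: float) -> str:
    return "vigorous" if level >= 6.0 else "moderate"


def simulate_diary(
    true_week: TrueActivityWeek, traits: ParticipantTraits, config: SimConfig
) -> list[DiaryEntry]:
    """Diary entries for the bouts a participant would plausibly record.

    Only bouts longer than 10 min are eligible (the diary instruction);
    each is omitted with ``diary_omission_prob``, its perceived intensity is
    drawn from the confusion-matrix row of the true intensity, and the
    reported duration is scaled by the personal ``diary_bias``.
    """
    rng = _participant_rng(
        config, traits.seed_index, _WEEK_KEY, WEEK_INDEX[true_week.week], 1
    )
    m = np.asarray(config.diary_intensity_confusion, dtype=float)
    start_date = WEEK_STARTS[true_week.week]
    levels = ("light", "moderate", "vigorous")
    entries: list[DiaryEntry] = []
    for day, start_s, dur_s, level in true_week.bouts:
        if dur_s <= 600:
            continue
        if rng.random() < config.diary_omission_prob:
            continue
        true_idx = 2 if level >= 6.0 else 1
        perceived = levels[rng.choice(3, p=m[true_idx])]
        reported_min = max(0.5, round(dur_s / 60.0 * traits.diary_bias, 1))
        entries.append(
            DiaryEntry(
                participant_id=true_week.participant_id,
                week=true_week.week,
                date=(start_date + pd.Timedelta(days=day)).date(),
                duration_min=reported_min,
                perceived_intensity=perceived,
                start_time=f"{start_s // 3600:02d}:{(start_s % 3600) // 60:02d}",
                activity_type="",
            )
        )
    return entries


def _round_to_grid(minutes: float, grid: float) -> float:
    if minutes <= 0:
        return 0.0
    return max(grid, round(minutes / grid) * grid)


def simulate_ipaq(
    true_week: TrueActivityWeek, traits: ParticipantTraits, config: SimConfig
) -> IpaqResponse:
    """Recall the week as IPAQ items: days x minutes/day on a rounding grid.

    The recalled volume is ``ipaq_overreport_factor * ipaq_bias * truth``;
    day counts are the distinct days with bouts of that intensity, and the
    participant's ``walk_fraction`` of recalled MPA is attributed to walking.
    """
    mpa_days = sorted({d for d, _, _, lv in true_week.bouts if lv < 6.0})
    vpa_days = sorted({d for d, _, _, lv in true_week.bouts if lv >= 6.0})
    factor = config.ipaq_overreport_factor * traits.ipaq_bias
    grid = config.ipaq_rounding_grid_min

    def items(volume_min: float, days: int) -> tuple[int, float]:
        if volume_min <= 0 or days == 0:
            return 0, 0.0
        return days, _round_to_grid(volume_min / days, grid)

    vpa_vol = factor * true_week.true_vpa_min
    mpa_vol = factor * true_week.true_mpa_min
    vig_days, vig_min = items(vpa_vol, max(1, len(vpa_days)) if vpa_vol > 0 else 0)
    walk_vol = traits.walk_fraction * mpa_vol
    mod_vol = mpa_vol - walk_vol
    n_mpa_days = max(1, len(mpa_days)) if mpa_vol > 0 else 0
    mod_days, mod_min = items(mod_vol, n_mpa_days)
    walk_days, walk_min = items(walk_vol, n_mpa_days)
    return IpaqResponse(
        participant_id=true_week.participant_id,
        week=true_week.week,
        vig_days=vig_days,
        vig_min_per_day=vig_min,
        mod_days=mod_days,
        mod_min_per_day=mod_min,
        walk_days=walk_days,
        walk_min_per_day=walk_min,
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, in memory."""

    config: SimConfig
    traits: list[ParticipantTraits]
    estimates: pd.DataFrame  # participant_id, population, week, tool, intensity, minutes_per_week, flags
    truth: pd.DataFrame  # participant_id, week, true_mpa_min, true_vpa_min
    diaries: dict = field(default_factory=dict)  # (pid, week) -> list[DiaryEntry]
    ipaqs: dict = field(default_factory=dict)  # (pid, week) -> IpaqResponse
    met_series: list = field(default_factory=list)  # kept only on request


def simulate_dataset(
    config: SimConfig,
    analysis_epochs: Sequence[int] = (10, 60),
    weeks: Sequence[str] = WEEKS,
    keep_met: bool = False,
    traits: Sequence[ParticipantTraits] | None = None,
) -> SimulatedDataset:
    """Simulate the cohort and run every measurement tool on it.

    Children get no IPAQ rows (their questionnaire yields no minutes/week).
    ``traits`` may be supplied to reuse a cohort (e.g., for null simulations
    pairing weeks from different cohorts).
    """
    for e in analysis_epochs:
        if e % config.base_epoch_s != 0:
            raise ConfigurationError(
                f"analysis epoch {e}s is not a multiple of base_epoch_s={config.base_epoch_s}"
            )
    cohort = list(traits) if traits is not None else generate_cohort(config)
    est_rows: list[WeeklyEstimate] = []
    populations: dict[str, str] = {}
    truth_rows = []
    diaries, ipaqs, met_list = {}, {}, []
    for t in cohort:
        populations[t.participant_id] = t.population
        for week in weeks:
            truth, series = simulate_week(t, week, config)
            truth_rows.append(
                {
                    "participant_id": t.participant_id,
                    "week": week,
                    "true_mpa_min": truth.true_mpa_min,
                    "true_vpa_min": truth.true_vpa_min,
                }
            )
            for e in analysis_epochs:
                est_rows.extend(acc_weekly_estimates(series, e))
            entries = simulate_diary(truth, t, config)
            diaries[(t.participant_id, week)] = entries
            est_rows.extend(
                score_diary(entries, participant_id=t.participant_id, week=week)
            )
            if t.population == "adult":
                resp = simulate_ipaq(truth, t, config)
                ipaqs[(t.participant_id, week)] = resp
                est_rows.extend(score_ipaq(resp))
            if keep_met:
                met_list.append(series)

    from .accelerometry import estimates_to_frame

    est = estimates_to_frame(est_rows)
    est.insert(1, "population", est["participant_id"].map(populations))
    return SimulatedDataset(
        config=config,
        traits=cohort,
        estimates=est,
        truth=pd.DataFrame(
            truth_rows, columns=["participant_id", "week", "true_mpa_min", "true_vpa_min"]
        ),
        diaries=diaries,
        ipaqs=ipaqs,
        met_series=met_list,
    )


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
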