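"""Synthetic acoustic-telemetry generator with known ground truth.

Emulates a two-island receiver study: two arrays (18 + 14 stations by
default) with staggered deployment windows and four habitat classes, a
cohort of tiger sharks spanning 91-300 cm fork length with a
female-skewed sex ratio, and time-stamped detections with imperfect
detection and injected false records.

Movement is a continuous-time Markov chain over {stations + off-array}:
while resident at a station a shark initiates a station-to-station move
at a rate set by its sex-specific motility effect — linear in fork
length for males, a Gaussian bump (default peak 237.5 cm) for females —
or departs the array; away spells end at a return rate that drops in
summer months to mimic seasonal emigration.  Destination choice is
distance-weighted.  Fork length grows through time under the growth
schedule, so life stage (and motility) can change mid-track.

Every visit is long enough to contain at least one transmission
interval, so with detection probability 1, full deployment coverage and
no false detections the pipeline can reconstruct the true visit
sequence exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .growth import DEFAULT_SCHEDULE, GrowthSchedule

__all__ = [
    "SimConfig",
    "TruthRecord",
    "ConfigError",
    "simulate_array",
    "simulate_cohort_and_tracks",
    "emit_detections",
    "true_movement_counts",
]

HABITATS = ("coral reef", "deep wall", "sand", "seagrass")
# study-wide habitat mix: 9 coral reef, 6 deep wall, 3 sand, 14 seagrass of 32
HABITAT_PROPORTIONS = {"coral reef": 9 / 32, "deep wall": 6 / 32, "sand": 3 / 32,
                       "seagrass": 14 / 32}
DEPTH_RANGES_M = {
    "coral reef": (3.0, 35.0),
    "deep wall": (60.0, 207.0),
    "sand": (2.0, 20.0),
    "seagrass": (2.0, 10.0),
}
ARRAY_CENTERS = {"NewProvidence": (25.03, -77.40), "GreatExuma": (23.50, -75.80)}
KM_PER_DEG = 111.0


class ConfigError(ValueError):
    """Invalid simulator configuration; message names the field."""


@dataclass
class SimConfig:
    """Simulator configuration; defaults mirror the study conditions."""

    seed: int = 0
    n_stations_per_array: tuple[int, int] = (18, 14)
    array_names: tuple[str, str] = ("NewProvidence", "GreatExuma")
    study_start: str = "2018-02-01"
    study_end: str = "2019-07-31"
    staggered_deployments: bool = True
    install_jitter_days: int = 60
    early_removal_frac: float = 0.15

    cohort_size: int = 40
    fl_range_cm: tuple[float, float] = (91.0, 300.0)
    male_fl_range_cm: tuple[float, float] = (140.0, 253.0)
    fl_mean_sd_female: tuple[float, float] = (218.0, 49.0)
    fl_mean_sd_male: tuple[float, float] = (209.0, 45.0)
    sex_ratio_female: float = 30 / 39
    min_track_days: int = 150

    # movement model: the sex-specific motility effect (0..1; linear in
    # FL for males, Gaussian bump for females) scales both the
    # station-to-station move rate and the home-range radius
    mean_away_h: float = 72.0
    away_heterogeneity_sd: float = 0.35  # lognormal sigma on per-shark away time
    leave_to_away_rate_per_h: float = 0.25
    move_rate_lo_hi_per_h: tuple[float, float] = (0.03, 0.16)
    home_range_lo_hi_km: tuple[float, float] = (4.0, 22.0)
    effect_floor: float = 0.10
    female_peak_fl_cm: float = 237.5
    female_peak_sd_cm: float = 35.0
    pref_scale_km: float = 5.0
    p_cross_array: float = 0.01
    swim_speed_kmh: float = 4.0
    summer_emigration: bool = True
    summer_months: tuple[int, ...] = (6, 7, 8, 9)
    summer_return_factor: float = 0.35

    # detection model
    detection_prob: float = 0.6
    ping_delay_s: tuple[float, float] = (120.0, 300.0)
    false_detection_rate: float = 0.05  # spurious detections per tag-day
    isolation_window_h: float = 24.0

    growth_schedule: GrowthSchedule = field(default=DEFAULT_SCHEDULE)

    def validate(self) -> None:
        if any(n < 1 for n in self.n_stations_per_array):
            raise ConfigError("n_stations_per_array: need >= 1 station per array")
        if self.cohort_size < 1:
            raise ConfigError("cohort_size: must be positive")
        lo, hi = self.fl_range_cm
        if not lo < hi:
            raise ConfigError("fl_range_cm: min must be < max")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ConfigError("sex_ratio_female: must lie in [0, 1]")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigError("detection_prob: must lie in [0, 1]")
        dlo, dhi = self.ping_delay_s
        if not (0 < dlo <= dhi):
            raise ConfigError("ping_delay_s: need 0 < min <= max")
        if self.false_detection_rate < 0:
            raise ConfigError("false_detection_rate: must be >= 0")
        if pd.Timestamp(self.study_end) <= pd.Timestamp(self.study_start):
            raise ConfigError("study_end: must follow study_start")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "growth_schedule" in raw:
            raw["growth_schedule"] = GrowthSchedule.from_frame(
                pd.DataFrame(raw["growth_schedule"])
            )
        for key in (
            "n_stations_per_array", "array_names", "fl_range_cm",
            "male_fl_range_cm", "fl_mean_sd_female", "fl_mean_sd_male",
            "male_rate_lo_hi_per_h", "ping_delay_s", "summer_months",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def motility_effect(self, fl_cm: float, sex: str) -> float:
        """Normalised motility effect in [effect_floor, 1].

        Males: monotone increasing (linear) in fork length over the male
        size range.  Females: unimodal Gaussian bump peaking at
        ``female_peak_fl_cm``.
        """
        if sex == "M":
            lo, hi = self.male_fl_range_cm
            raw = float(np.clip((fl_cm - lo) / (hi - lo), 0.0, 1.0))
        else:
            z = (fl_cm - self.female_peak_fl_cm) / self.female_peak_sd_cm
            raw = math.exp(-0.5 * z * z)
        return self.effect_floor + (1.0 - self.effect_floor) * raw

    def motility_rate(self, fl_cm: float, sex: str) -> float:
        """Station-to-station move rate (per hour) for a shark of given size."""
        r0, r1 = self.move_rate_lo_hi_per_h
        return r0 + (r1 - r0) * self.motility_effect(fl_cm, sex)

    def home_range_km(self, fl_cm: float, sex: str) -> float:
        """Home-range radius (km) for a shark of given size."""
        h0, h1 = self.home_range_lo_hi_km
        return h0 + (h1 - h0) * self.motility_effect(fl_cm, sex)


@dataclass
class TruthRecord:
    """Ground truth for one simulated shark (testing only)."""

    shark_id: str
    sex: str
    fl_tagging_cm: float
    tagging_datetime: pd.Timestamp
    visits: pd.DataFrame  # station_id, array, arrive, depart (time-ordered)
    fl_by_day: pd.Series  # date -> fork length cm
    rate_at_tagging_per_h: float

    def fl_at(self, when) -> float:
        d = pd.Timestamp(when).normalize()
        idx = self.fl_by_day.index
        d = min(max(d, idx[0]), idx[-1])
        return float(self.fl_by_day.loc[d])


def _largest_remainder(total: int, proportions: dict[str, float]) -> dict[str, int]:
    raw = {k: total * p for k, p in proportions.items()}
    base = {k: int(v) for k, v in raw.items()}
    short = total - sum(base.values())
    order = sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def simulate_array(config: SimConfig) -> pd.DataFrame:
    """Generate the receiver-station table (one row per deployment)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    rows = []
    for a_idx, (array, n) in enumerate(
        zip(config.array_names, config.n_stations_per_array)
    ):
        habitat_counts = _largest_remainder(n, HABITAT_PROPORTIONS)
        habitats = [h for h, c in habitat_counts.items() for _ in range(c)]
        rng.shuffle(habitats)
        lat0, lon0 = ARRAY_CENTERS.get(array, (24.0 + a_idx, -77.0 + 1.5 * a_idx))
        prefix = array[0].upper() if array else "S"
        for i in range(n):
            habitat = habitats[i]
            dlo, dhi = DEPTH_RANGES_M[habitat]
            install = start
            removal = end
            if config.staggered_deployments and i > 0:
                install = start + pd.Timedelta(
                    days=int(rng.integers(0, config.install_jitter_days + 1))
                )
                if rng.random() < config.early_removal_frac:
                    span = (end - install).days
                    removal = install + pd.Timedelta(
                        days=int(span * rng.uniform(0.6, 0.9))
                    )
            rows.append(
                {
                    "station_id": f"{prefix}{i + 1}",
                    "array": array,
                    "latitude": lat0 + rng.uniform(-0.15, 0.15),
                    "longitude": lon0 + rng.uniform(-0.2, 0.2),
                    "depth_m": round(rng.uniform(dlo, dhi), 1),
                    "habitat": habitat,
                    "install_date": install,
                    "removal_date": removal,
                }
            )
    return pd.DataFrame(rows)


def _station_distances(receivers: pd.DataFrame) -> tuple[dict, np.ndarray, list]:
    st = receivers.drop_duplicates("station_id").reset_index(drop=True)
    ids = st["station_id"].tolist()
    lat = st["latitude"].to_numpy()
    lon = st["longitude"].to_numpy()
    mean_lat = np.deg2rad(lat.mean())
    dx = (lon[:, None] - lon[None, :]) * KM_PER_DEG * np.cos(mean_lat)
    dy = (lat[:, None] - lat[None, :]) * KM_PER_DEG
    dist = np.hypot(dx, dy)
    index = {s: i for i, s in enumerate(ids)}
    return index, dist, ids


def simulate_cohort_and_tracks(
    config: SimConfig, receivers: pd.DataFrame
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Draw a shark cohort and simulate ground-truth movement tracks."""
    config.validate()
    stations = receivers.drop_duplicates("station_id")
    if len(stations) < 2:
        raise ConfigError("n_stations_per_array: movement needs >= 2 stations")
    rng = np.random.default_rng([config.seed, 2])
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    idx, dist, ids = _station_distances(receivers)
    array_of = stations.set_index("station_id")["array"].to_dict()
    arrays = list(dict.fromkeys(stations["array"]))
    by_array = {a: [idx[s] for s in ids if array_of[s] == a] for a in arrays}

    tag_rows = []
    truths = []
    for k in range(config.cohort_size):
        shark_id = f"TS{k + 1:03d}"
        sex = "F" if rng.random() < config.sex_ratio_female else "M"
        if sex == "F":
            mean, sd = config.fl_mean_sd_female
            lo, hi = config.fl_range_cm
        else:
            mean, sd = config.fl_mean_sd_male
            lo, hi = config.male_fl_range_cm
        fl = float(np.clip(rng.normal(mean, sd), lo, hi))
        max_tag_day = max((end - start).days - config.min_track_days, 1)
        tagging = start + pd.Timedelta(
            days=int(rng.integers(0, max_tag_day)), hours=int(rng.integers(6, 18))
        )
        tag_array = arrays[int(rng.integers(len(arrays)))]
        tag_rows.append(
            {
                "shark_id": shark_id,
                "tag_id": f"A69-{9001 + k}",
                "tagging_datetime": tagging,
                "tagging_array": tag_array,
                "fl_tagging_cm": round(fl, 1),
                "sex": sex,
                "claspers_calcified": sex == "M" and fl > 250,
                "min_delay_s": config.ping_delay_s[0],
                "max_delay_s": config.ping_delay_s[1],
            }
        )

        # daily fork-length trajectory under the growth schedule
        n_days = (end.normalize() - tagging.normalize()).days + 1
        fls = np.empty(n_days)
        f = fl
        sched = config.growth_schedule
        for d in range(n_days):
            fls[d] = f
            f = min(f + sched.rate_at(f) / 365.0, sched.fl_max)
        fl_by_day = pd.Series(
            fls, index=pd.date_range(tagging.normalize(), periods=n_days)
        )

        away_mult = float(
            rng.lognormal(0.0, config.away_heterogeneity_sd)
            if config.away_heterogeneity_sd > 0
            else 1.0
        )
        visits = _simulate_track(
            config, rng, fl_by_day, sex, tagging, end, dist, by_array, ids,
            array_of, tag_array, away_mult,
        )
        truths.append(
            TruthRecord(
                shark_id=shark_id,
                sex=sex,
                fl_tagging_cm=fl,
                tagging_datetime=tagging,
                visits=visits,
                fl_by_day=fl_by_day,
                rate_at_tagging_per_h=config.motility_rate(fl, sex),
            )
        )
    return pd.DataFrame(tag_rows), truths


def _simulate_track(
    config, rng, fl_by_day, sex, tagging, end, dist, by_array, ids, array_of,
    tag_array, away_mult: float = 1.0,
) -> pd.DataFrame:
    """CTMC over stations + off-array; returns the visit table.

    Destination and return choices are weighted by proximity to the
    current station and to the shark's per-array home station, with the
    home-range scale set by the (size- and sex-dependent) motility
    effect, so larger effects produce both more and wider movements.
    """
    min_visit_h = config.ping_delay_s[1] / 3600.0
    cur = int(rng.choice(by_array[tag_array]))
    home = {tag_array: cur}
    t = tagging
    visits = []

    def _pick(pool, fl):
        rho = config.home_range_km(fl, sex)
        h = home[array_of[ids[pool[0]]]]
        w = np.exp(-dist[cur, pool] / config.pref_scale_km) * np.exp(
            -dist[h, pool] / rho
        )
        if w.sum() <= 0:
            w = np.ones(len(pool))
        return int(rng.choice(pool, p=w / w.sum()))

    while t < end:
        # --- resident at station `cur`
        if (end - t) < pd.Timedelta(hours=min_visit_h):
            break  # too short to hold a transmission interval
        d = min(max(t.normalize(), fl_by_day.index[0]), fl_by_day.index[-1])
        fl = float(fl_by_day.loc[d])
        lam_move = config.motility_rate(fl, sex)
        lam_away = config.leave_to_away_rate_per_h
        hold_h = min_visit_h + rng.exponential(1.0 / (lam_move + lam_away))
        depart = min(t + pd.Timedelta(hours=hold_h), end)
        visits.append(
            {
                "station_id": ids[cur],
                "array": array_of[ids[cur]],
                "arrive": t,
                "depart": depart,
            }
        )
        t = depart
        if t >= end:
            break
        if rng.random() < lam_move / (lam_move + lam_away):
            # direct station-to-station move within the array
            pool = [j for j in by_array[array_of[ids[cur]]] if j != cur]
            if not pool:
                continue
            nxt = _pick(pool, fl)
            travel_h = dist[cur, nxt] / config.swim_speed_kmh
            t = t + pd.Timedelta(hours=travel_h)
            cur = nxt
        else:
            # off-array spell; return rate drops in summer
            mean_away = config.mean_away_h * away_mult
            if config.summer_emigration and t.month in config.summer_months:
                mean_away /= config.summer_return_factor
            away_h = rng.exponential(mean_away)
            t = t + pd.Timedelta(hours=away_h)
            if t >= end:
                break
            if rng.random() < config.p_cross_array and len(by_array) > 1:
                other = [a for a in by_array if a != array_of[ids[cur]]][0]
                cur = int(rng.choice(by_array[other]))
                home.setdefault(other, cur)
            else:
                cur = _pick(by_array[array_of[ids[cur]]], fl)
    return pd.DataFrame(visits, columns=["station_id", "array", "arrive", "depart"])


def emit_detections(
    truths: list[TruthRecord],
    receivers: pd.DataFrame,
    config: SimConfig,
    tags: pd.DataFrame,
) -> pd.DataFrame:
    """Turn ground-truth visits into a detection stream.

    Pings occur at uniform-random transmission delays during each visit,
    are dropped when the station is not deployed, and survive with
    ``detection_prob``.  False detections are injected in two classes —
    impossible short-interval duplicates and isolated singletons — and
    flagged in ``truth_flag`` (testing only; writers drop the column).
    """
    if not truths:
        raise ValueError("emit_detections: empty truth list")
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    dlo, dhi = config.ping_delay_s
    deployments = {
        sid: [
            (r.install_date, r.removal_date if pd.notna(r.removal_date) else pd.Timestamp.max)
            for r in grp.itertuples()
        ]
        for sid, grp in receivers.groupby("station_id")
    }
    tag_of = tags.set_index("shark_id")["tag_id"].to_dict()
    end = pd.Timestamp(config.study_end)

    frames = []
    for truth in truths:
        tag_id = tag_of[truth.shark_id]
        times = []
        stations = []
        for v in truth.visits.itertuples():
            dur_s = (v.depart - v.arrive).total_seconds()
            if dur_s <= 0:
                continue
            n_est = int(dur_s / dlo) + 2
            offs = np.cumsum(rng.uniform(dlo, dhi, size=n_est))
            offs = offs[offs <= dur_s]
            # visits are at least one max-delay long by construction, so
            # every visit carries at least one transmission
            if offs.size == 0 and dur_s > dlo:
                offs = np.array([rng.uniform(dlo, min(dhi, dur_s))])
            ping_t = v.arrive + pd.to_timedelta(offs, unit="s")
            ok = np.zeros(len(ping_t), dtype=bool)
            for lo, hi in deployments.get(v.station_id, []):
                ok |= (ping_t >= lo) & (ping_t <= hi)
            if config.detection_prob < 1.0:
                ok &= rng.random(len(ping_t)) < config.detection_prob
            times.extend(ping_t[ok])
            stations.extend([v.station_id] * int(ok.sum()))
        real = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(times),
                "tag_id": tag_id,
                "station_id": stations,
                "truth_flag": "real",
            }
        )
        frames.append(real)
        frames.append(_inject_false(rng, real, truth, config, tag_id, end))

    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["timestamp", "tag_id", "station_id", "truth_flag"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["timestamp", "tag_id", "station_id"]).reset_index(
        drop=True
    )


def _inject_false(rng, real, truth, config, tag_id, end) -> pd.DataFrame:
    tag_days = max((end - truth.tagging_datetime).days, 1)
    n_false = rng.poisson(config.false_detection_rate * tag_days)
    if n_false == 0 or config.false_detection_rate == 0:
        return pd.DataFrame(columns=["timestamp", "tag_id", "station_id", "truth_flag"])
    rows = []
    n_short = n_false // 2
    win = pd.Timedelta(hours=config.isolation_window_h)
    if len(real) >= 2:
        ts = real["timestamp"].to_numpy()
        gaps_ok = np.zeros(len(real), dtype=bool)
        gaps_ok[1:] |= (ts[1:] - ts[:-1]) <= win.to_numpy()
        gaps_ok[:-1] |= (ts[1:] - ts[:-1]) <= win.to_numpy()
        candidates = np.flatnonzero(gaps_ok)
        for _ in range(n_short):
            if candidates.size == 0:
                break
            i = int(rng.choice(candidates))
            offset = rng.uniform(1.0, max(config.ping_delay_s[0] - 1.0, 1.5))
            rows.append(
                {
                    "timestamp": real["timestamp"].iloc[i]
                    + pd.Timedelta(seconds=offset),
                    "tag_id": tag_id,
                    "station_id": real["station_id"].iloc[i],
                    "truth_flag": "false_short_interval",
                }
            )
    all_stations = truth.visits["station_id"].unique()
    if len(real) and len(all_stations):
        ts_sorted = np.sort(real["timestamp"].to_numpy())
        span_s = (end - truth.tagging_datetime).total_seconds()
        for _ in range(n_false - n_short):
            for _try in range(20):
                t = truth.tagging_datetime + pd.Timedelta(
                    seconds=rng.uniform(0, span_s)
                )
                j = np.searchsorted(ts_sorted, np.datetime64(t))
                near = []
                if j > 0:
                    near.append(abs((t - pd.Timestamp(ts_sorted[j - 1]))))
                if j < len(ts_sorted):
                    near.append(abs((pd.Timestamp(ts_sorted[j]) - t)))
                if not near or min(near) > win:
                    rows.append(
                        {
                            "timestamp": t,
                            "tag_id": tag_id,
                            "station_id": str(rng.choice(all_stations)),
                            "truth_flag": "false_isolated",
                        }
                    )
                    break
    return pd.DataFrame(rows, columns=["timestamp", "tag_id", "station_id", "truth_flag"])


def true_movement_counts(truth: TruthRecord) -> dict[str, int]:
    """Station-change counts in the true visit sequence, per array.

    Adjacent visits at different stations of the same array count one
    movement (matching the consecutive-detection definition downstream);
    array changes are counted under ``"inter_array"``.
    """
    counts: dict[str, int] = {"inter_array": 0}
    v = truth.visits
    seq = list(zip(v["station_id"], v["array"]))
    for (s1, a1), (s2, a2) in zip(seq, seq[1:]):
        if s1 == s2:
            continue
        if a1 == a2:
            counts[a1] = counts.get(a1, 0) + 1
        else:
            counts["inter_array"] += 1
    return counts
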