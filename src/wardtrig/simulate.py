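"""Synthetic ward study generator.

Everything the analysis pipeline consumes can be simulated here with known
generative parameters: per-room environmental sensor streams, per-patient
room-occupancy traces (including off-map time and visits to sensorless
rooms), a semirandom nurse-prompt schedule, and momentary agitation
outcomes drawn from logistic models whose environmental inputs are the
standardized features of the causal pre-survey window.  Because the truth
is known, every downstream stage can be validated by parameter recovery.

Outcome generation (default mode):

* motor  ~ Bernoulli(expit(α_m + β_light_mean·z_light_mean + time + room + b_i))
* verbal ~ Bernoulli(expit(α_v + β_sound_sd·z_sound_sd + time + room + b_i
  + κ·motor))

with one shared patient intercept b_i ~ N(0, σ_b²); κ ≥ 0 adds per-survey
motor→verbal co-occurrence on top of the shared susceptibility.  Overall
agitation is the OR of all four PAS subtypes (a small rate of
resistance-to-care / aggression scores produces agitated surveys that are
neither motor nor verbal).  The z-features planted by the generator are the
realized causal-window features standardized within the majority room over
all scheduled windows of the study — i.e. the planted coefficients are
exactly the log-odds-per-SD effects of the features the study design
produced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import OutcomeParams, SimulationConfig
from .dataset import MODALITIES, LocationTrace, SensorTable, StudyDataset
from .features import FEATURE_NAMES, assign_time_group, compute_features
from .layout import OFF_MAP, WardLayout, default_layout
from .windowing import WindowSpec, extract_window

# ---------------------------------------------------------------------------
# sensor streams


def _diurnal(hours: np.ndarray, amp: float, peak_h: float) -> np.ndarray:
    return amp * np.cos(2.0 * np.pi * (hours - peak_h) / 24.0)


def simulate_sensor_streams(
    layout: WardLayout, config: SimulationConfig,
    rng: np.random.Generator,
) -> SensorTable:
    """One reading per sensor per sample period per modality.

    Light is lognormal around a per-room-group base level with a diurnal
    log-amplitude peaking at 14:00 (dim ward: room medians in the tens of
    lux).  Sound is a Gaussian base with a daytime bump plus sporadic
    positive bursts (events on the ward).  Temperature drifts slowly around
    a per-room setpoint.  The two enclosures of a dual-sensor room share
    the room profile but carry independent noise.
    """
    span = config.study_span_s
    period = config.sample_period
    n = span // period
    if n <= 0:
        raise ValueError("study span must contain at least one sample")
    t = np.arange(n, dtype=np.int64) * period
    hours = (t % 86400) / 3600.0
    d_light = _diurnal(hours, config.light_diurnal_amp, 14.0)
    d_sound = _diurnal(hours, config.sound_diurnal_amp, 13.0)
    d_temp = _diurnal(hours, config.temp_diurnal_amp, 15.0)

    temp_offsets = {
        r.room_id: rng.normal(0.0, config.temp_room_sd) if config.temp_room_sd
        else 0.0
        for r in layout.rooms
    }
    # slow drifts: white knots linearly interpolated (≈ knot-spacing
    # correlation time); one independent realization per sensor & modality
    tf = t.astype(np.float64)
    knot_slow = np.arange(0, span + 1800, 1800, dtype=np.float64)   # 30 min
    knot_temp = np.arange(0, span + 3600, 3600, dtype=np.float64)   # 1 h

    def slow(knots_t: np.ndarray, sd: float) -> np.ndarray | float:
        if sd <= 0:
            return 0.0
        return np.interp(tf, knots_t, rng.normal(0.0, sd, len(knots_t)))

    values: dict[tuple[str, str], np.ndarray] = {}
    sensor_room: dict[str, str] = {}
    for sensor_id, room_id in layout.all_sensors:
        group = layout.group_of(room_id)
        sensor_room[sensor_id] = room_id

        log_lux = (config.log_light_base[group] + d_light
                   + slow(knot_slow, config.light_slow_sd))
        if config.light_noise_sd > 0:
            log_lux = log_lux + rng.normal(0.0, config.light_noise_sd, n)
        values[(sensor_id, "light")] = np.exp(log_lux).astype(np.float32)

        snd = (config.sound_base[group] + d_sound
               + slow(knot_slow, config.sound_slow_sd))
        if config.sound_noise_sd > 0:
            snd = snd + rng.normal(0.0, config.sound_noise_sd, n)
        p_burst = config.sound_burst_rate * period
        if p_burst > 0 and config.sound_burst_amp > 0:
            mask = rng.random(n) < p_burst
            k = int(mask.sum())
            if k:
                snd = np.asarray(snd, dtype=np.float64).copy()
                snd[mask] += rng.exponential(config.sound_burst_amp, k)
        values[(sensor_id, "sound")] = np.asarray(snd, np.float32)

        tmp = (config.temp_setpoint + temp_offsets[room_id] + d_temp
               + slow(knot_temp, config.temp_noise_sd))
        values[(sensor_id, "temperature")] = np.asarray(tmp, np.float32)

    return SensorTable(0, period, n, values, sensor_room)


# ---------------------------------------------------------------------------
# location traces


def _destinations(layout: WardLayout, home_room: str,
                  config: SimulationConfig):
    """Visit targets with probabilities; weights split within room groups."""
    rooms: list[str] = []
    probs: list[float] = []

    def add_group(group: str, weight: float) -> None:
        ids = [r.room_id for r in layout.rooms
               if r.group == group and r.room_id != home_room]
        for rid in ids:
            rooms.append(rid)
            probs.append(weight / len(ids))

    w = config.visit_weights
    rooms.append(home_room)
    probs.append(w.get("home", 0.0))
    add_group("living room", w.get("living room", 0.0))
    add_group("dining room", w.get("dining room", 0.0))
    add_group("hallway", w.get("hallway", 0.0))
    add_group("other", w.get("other", 0.0))
    p = np.asarray(probs, dtype=np.float64)
    return rooms, p / p.sum()


def _unit_lognormal(rng, size: int, sigma: float = 0.5) -> np.ndarray:
    """Lognormal draws with mean 1 (dwell shape; scaled by the group mean)."""
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def simulate_location_trace(
    patient_id: str, layout: WardLayout, config: SimulationConfig,
    rng: np.random.Generator, home_room: str | None = None,
) -> LocationTrace:
    """Semi-Markov room-occupancy trace covering the whole study span.

    Sojourns are lognormal with room-group-dependent means; after each room
    visit an off-map gap (wearable not worn / untracked location) is
    inserted with a probability solved so the long-run off-map time
    fraction matches ``config.off_map_fraction``.
    """
    if home_room is None:
        home_room = next(r.room_id for r in layout.rooms
                         if r.group == "patient room")
    span = float(config.study_span_s)
    rooms_d, probs = _destinations(layout, home_room, config)
    group_of = {rid: layout.group_of(rid) for rid in rooms_d}
    mean_dwell_s = np.array(
        [config.dwell_min[group_of[r]] * 60.0 for r in rooms_d])
    mu_room = float(probs @ mean_dwell_s)
    mu_off = config.off_map_dwell_min * 60.0
    f = config.off_map_fraction
    # expected off-map time per room visit that yields fraction f; realized
    # either as a sub-unit insertion probability or, when one gap per visit
    # is not enough, as longer gaps (wearable off for extended stretches)
    target_off = f * mu_room / (1.0 - f) if f > 0 else 0.0
    if target_off <= mu_off:
        q = target_off / mu_off if mu_off > 0 else 0.0
    else:
        q, mu_off = 1.0, target_off

    rooms: list[str] = []
    durs: list[float] = []
    total = 0.0
    while total < span:
        k = max(16, int((span - total) / (mu_room + q * mu_off) * 1.3))
        idx = rng.choice(len(rooms_d), size=k, p=probs)
        dw = np.maximum(30.0, _unit_lognormal(rng, k) * mean_dwell_s[idx])
        off = rng.random(k) < q
        off_dw = np.maximum(30.0, _unit_lognormal(rng, k) * mu_off)
        for i in range(k):
            rooms.append(rooms_d[idx[i]])
            durs.append(dw[i])
            total += dw[i]
            if off[i]:
                rooms.append(OFF_MAP)
                durs.append(off_dw[i])
                total += off_dw[i]
            if total >= span:
                break

    ends = np.minimum(np.round(np.cumsum(durs)), span).astype(np.int64)
    keep = np.concatenate(([ends[0] > 0], np.diff(ends) > 0))
    ends = ends[keep]
    starts = np.concatenate(([0], ends[:-1]))
    return LocationTrace(patient_id, starts, ends,
                         np.asarray(rooms, dtype=object)[keep])


# ---------------------------------------------------------------------------
# EMA schedule


def schedule_emas(day: int, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Semirandom nurse-prompt times for one day (seconds, ward clock).

    The prompt window is split into ``prompts_per_day`` equal sub-bins and
    one prompt is placed uniformly (1-minute resolution) inside each bin —
    stratified, so prompts spread over the day without being periodic.
    Minimum spacing is deliberately not enforced; adjacent prompts may have
    overlapping analysis windows, as in reality.
    """
    w0, w1 = config.prompt_window
    total_min = (w1 - w0) * 60
    k = config.prompts_per_day
    if k > total_min:
        raise ValueError("more prompts than 1-minute sub-bins in the window")
    edges = np.linspace(0.0, total_min, k + 1)
    lo = np.ceil(edges[:-1]).astype(np.int64)
    hi = np.ceil(edges[1:]).astype(np.int64) - 1
    minutes = rng.integers(lo, hi + 1)
    return day * 86400 + (w0 * 60 + minutes) * 60


# ---------------------------------------------------------------------------
# outcomes


def _parse_feature_key(key: str) -> tuple[str, str]:
    for m in MODALITIES:
        prefix = m + "_"
        if key.startswith(prefix) and key[len(prefix):] in FEATURE_NAMES:
            return m, key[len(prefix):]
    raise ValueError(f"unknown environmental feature key {key!r}")


def _room_group_effect(params: OutcomeParams, group: str | None) -> float:
    if group is None:          # off-map majority; survey is filtered later
        return 0.0
    return params.room_group_betas.get(group, 0.0)


def _linear_predictor(params: OutcomeParams, z: dict[str, np.ndarray],
                      tg: np.ndarray, room_group: list[str | None],
                      b: np.ndarray) -> np.ndarray:
    lp = np.full(len(tg), params.intercept, dtype=np.float64)
    for key, beta in params.env_betas.items():
        lp += beta * z[key]
    tg_eff = np.array((0.0,) + tuple(params.time_group_betas))
    lp += tg_eff[tg - 1]
    lp += np.array([_room_group_effect(params, g) for g in room_group])
    return lp + b


def generate_outcomes(
    dataset: StudyDataset, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Draw PAS outcomes for every scheduled survey of ``dataset``.

    The causal inputs are the standardized features of the window
    ``[t - causal_start_offset, t - causal_end_offset)`` minutes before
    each survey, extracted with the same windowing code the analysis
    pipeline uses and z-scored within the majority room across all
    scheduled windows.  Windows without usable data (off-map, sensorless
    majority, undefined stratum) contribute no environmental effect.

    Returns (surveys with PAS scores, per-survey truth table, log lines).
    """
    log: list[str] = []
    params_list = [config.motor, config.verbal]
    if config.direct_agitation is not None:
        params_list.append(config.direct_agitation)
    needed = sorted({k for p in params_list for k in p.env_betas})
    needed_mods = tuple(sorted({_parse_feature_key(k)[0] for k in needed}))
    spec = WindowSpec(length_min=config.causal_length_min,
                      buffer_min=config.causal_buffer_min)

    sv = dataset.surveys.reset_index(drop=True)
    keep_mask = np.ones(len(sv), dtype=bool)
    raw = {k: np.full(len(sv), np.nan) for k in needed}
    maj_room: list[str] = []
    for i, row in enumerate(sv.itertuples(index=False)):
        w0, _ = spec.interval(row.t_s)
        if w0 < dataset.sensors.start_s:
            keep_mask[i] = False
            maj_room.append(OFF_MAP)
            log.append(f"{row.survey_id}: causal window precedes study start,"
                       " survey dropped")
            continue
        wd = extract_window(dataset, row.survey_id, row.patient_id, row.t_s,
                            spec, needed_mods)
        maj_room.append(wd.majority_room)
        feats = {m: compute_features(wd.series[m][1]) for m in needed_mods}
        for k in needed:
            m, f = _parse_feature_key(k)
            raw[k][i] = feats[m][f]

    sv = sv[keep_mask].reset_index(drop=True)
    maj = np.asarray(maj_room, dtype=object)[keep_mask]
    raw = {k: v[keep_mask] for k, v in raw.items()}

    # standardize within majority room over all scheduled windows
    z = {}
    for k, x in raw.items():
        zk = np.zeros(len(sv))
        for room in np.unique(maj):
            if room == OFF_MAP or not dataset.layout.has_sensor(str(room)):
                continue
            sel = (maj == room) & np.isfinite(x)
            if sel.sum() < 2:
                continue
            mu, sd = x[sel].mean(), x[sel].std(ddof=1)
            if sd > 0:
                zk[sel] = (x[sel] - mu) / sd
        z[k] = zk

    tg = np.array([assign_time_group(t) for t in sv["t_s"]], dtype=np.int64)
    room_group = [dataset.layout.group_of(r) if r != OFF_MAP else None
                  for r in maj]
    patients = sv["patient_id"].to_numpy()
    uniq = pd.unique(patients)
    b_map = dict(zip(uniq, rng.normal(0.0, config.sigma_b, len(uniq))))
    b = np.array([b_map[p] for p in patients])

    n = len(sv)
    pas = {c: np.zeros(n, dtype=np.int64) for c in
           ("pas_motor", "pas_verbal", "pas_resist", "pas_aggr")}

    def severity(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n, dtype=np.int64)
        out[mask] = rng.integers(1, 5, int(mask.sum()))
        return out

    truth = {"survey_id": sv["survey_id"].to_numpy(), "b": b,
             "majority_room": maj.astype(str), "time_group": tg}
    truth.update({f"z_{k}": v for k, v in z.items()})

    if config.direct_agitation is not None:
        lp = _linear_predictor(config.direct_agitation, z, tg, room_group, b)
        agit = rng.random(n) < expit(lp)
        pas["pas_resist"] = severity(agit)
        truth["lp_agitation"] = lp
        truth["agitation"] = agit.astype(int)
    else:
        lp_m = _linear_predictor(config.motor, z, tg, room_group, b)
        motor = rng.random(n) < expit(lp_m)
        lp_v = (_linear_predictor(config.verbal, z, tg, room_group, b)
                + config.kappa * motor)
        verbal = rng.random(n) < expit(lp_v)
        pas["pas_motor"] = severity(motor)
        pas["pas_verbal"] = severity(verbal)
        if config.p_other > 0:
            pas["pas_resist"] = severity(rng.random(n) < config.p_other)
            pas["pas_aggr"] = severity(rng.random(n) < config.p_other)
        truth.update({"lp_motor": lp_m, "lp_verbal": lp_v,
                      "motor": motor.astype(int), "verbal": verbal.astype(int)})

    out = sv.copy()
    for c, v in pas.items():
        out[c] = v

    # optional self-initiated EMAs: keep candidates preferentially when the
    # latent risk of the moment is high
    if "is_extra" in out.columns:
        extra = out["is_extra"].to_numpy(dtype=bool)
        if extra.any():
            if config.direct_agitation is not None:
                p_any = expit(truth["lp_agitation"])
            else:
                p_any = 1.0 - (1.0 - expit(truth["lp_motor"])) * (
                    1.0 - expit(truth["lp_verbal"]))
            keep = ~extra | (rng.random(n) < p_any)
            out = out[keep].reset_index(drop=True)
            truth = {k: np.asarray(v)[keep] for k, v in truth.items()}
            log.append(f"self-initiated EMAs: kept {int((keep & extra).sum())}"
                       f" of {int(extra.sum())} candidates")
        out = out.drop(columns=["is_extra"])

    return out, pd.DataFrame(truth), log


# ---------------------------------------------------------------------------
# full study


def simulate_study(config: SimulationConfig,
                   layout: WardLayout | None = None) -> StudyDataset:
    """Generate one complete study dataset; fully reproducible per seed."""
    if layout is None:
        layout = default_layout()
    ss = np.random.SeedSequence(config.seed)
    rng_streams, rng_traces, rng_sched, rng_out = (
        np.random.default_rng(s) for s in ss.spawn(4))

    sensors = simulate_sensor_streams(layout, config, rng_streams)

    patient_rooms = [r.room_id for r in layout.rooms
                     if r.group == "patient room"]
    patients = [f"p{i + 1:03d}" for i in range(config.n_patients)]
    traces = {}
    for i, pid in enumerate(patients):
        home = patient_rooms[i % len(patient_rooms)]
        traces[pid] = simulate_location_trace(pid, layout, config,
                                              rng_traces, home)

    rows = []
    for pid in patients:
        for day in range(config.days_per_patient):
            for t in schedule_emas(day, config, rng_sched):
                rows.append((pid, int(t), False))
            if config.extra_ema_rate > 0:
                n_extra = rng_sched.poisson(2.0 * config.extra_ema_rate)
                w0, w1 = config.prompt_window
                for t in rng_sched.integers(w0 * 3600, w1 * 3600, n_extra):
                    rows.append((pid, day * 86400 + int(t), True))
    sv = pd.DataFrame(rows, columns=["patient_id", "t_s", "is_extra"])
    sv = sv.sort_values(["patient_id", "t_s"]).reset_index(drop=True)
    sv.insert(0, "survey_id",
              [f"{p}_{i:04d}" for i, p in zip(sv.groupby("patient_id").cumcount(),
                                              sv["patient_id"])])

    dataset = StudyDataset(layout, sensors, traces, sv, config=config)
    surveys, truth, log = generate_outcomes(dataset, config, rng_out)
    dataset.surveys = surveys
    dataset.truth = truth
    dataset.log = log
    return dataset
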