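"""Simulation and pipeline configuration.

All knobs of the synthetic ward generator live in :class:`SimulationConfig`.
Defaults describe one study: a week of 1 Hz ambient sensing (light in lux,
A-weighted equivalent sound level in dBA, temperature in °C), nine
semirandom nurse prompts per patient per day between 08:00 and 20:00, and
momentary agitation outcomes driven by standardized environmental features
of the window 33 to 12 minutes before each survey.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

#: smoothing span (seconds) of the trailing moving average applied to each
#: extracted window series; the sample period must divide it.
SMOOTHING_SPAN_S = 5


class OutcomeParams(BaseModel):
    """Logistic generative model for one binary agitation channel.

    Linear predictor: intercept + Σ env_betas·z_feature + time-group effect
    + room-group effect + patient random intercept (+ coupling, see
    :class:`SimulationConfig.kappa`).  ``env_betas`` keys are
    ``"<modality>_<feature>"`` names, e.g. ``"sound_sd"``, ``"light_mean"``;
    the z-features are the standardized causal-window features, so each β is
    a log-odds change per 1 SD.
    """

    intercept: float
    env_betas: dict[str, float] = Field(default_factory=dict)
    #: effects of time-of-day groups 2..4 relative to group 1 ([8,12))
    time_group_betas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: effects of majority-room groups relative to "living room"
    room_group_betas: dict[str, float] = Field(default_factory=dict)


def _default_motor() -> OutcomeParams:
    return OutcomeParams(
        intercept=-2.35,
        env_betas={"light_mean": -0.61},
        time_group_betas=(0.55, 0.90, 0.0),
        room_group_betas={
            "dining room": 0.30,
            "hallway": 0.95,
            "patient room": 0.20,
            "other": 0.30,
        },
    )


def _default_verbal() -> OutcomeParams:
    return OutcomeParams(
        intercept=-2.85,
        env_betas={"sound_sd": 0.68},
        time_group_betas=(0.10, 0.15, 0.0),
        room_group_betas={
            "dining room": 0.20,
            "hallway": 0.85,
            "patient room": 0.10,
            "other": 0.20,
        },
    )


class SimulationConfig(BaseModel):
    """Full parameterization of one synthetic ward study."""

    # -- study design ------------------------------------------------------
    n_patients: int = 30
    days_per_patient: int = 7
    sample_period: int = 1          # seconds between sensor readings
    prompts_per_day: int = 9
    prompt_window: tuple[int, int] = (8, 20)   # ward clock hours [start, end)

    # -- causal window (minutes before the survey timestamp) ---------------
    causal_start_offset: float = 33.0
    causal_end_offset: float = 12.0

    # -- sensor stream calibration -----------------------------------------
    # light: lognormal; log-lux = room base + diurnal cosine + white noise.
    # Calibrated so pooled room medians sit in the tens of lux (dim ward).
    log_light_base: dict[str, float] = Field(
        default_factory=lambda: {
            "living room": 3.5,
            "dining room": 3.4,
            "other": 3.4,
            "hallway": 2.9,
            "patient room": 3.1,
        }
    )
    light_diurnal_amp: float = 1.0      # log-lux amplitude, peak 14:00
    light_noise_sd: float = 0.6         # log-lux white noise
    #: slow per-sensor level drift (lights switched, blinds, occupancy);
    #: log-lux SD, ~30-min correlation; the modality-specific drifts are
    #: mutually independent so window features of different modalities are
    #: not confounded through a shared profile
    light_slow_sd: float = 0.45
    # sound: Gaussian base + sporadic positive bursts (events on the ward)
    sound_base: dict[str, float] = Field(
        default_factory=lambda: {
            "living room": 47.0,
            "dining room": 48.0,
            "other": 46.0,
            "hallway": 44.0,
            "patient room": 41.0,
        }
    )
    sound_diurnal_amp: float = 0.5      # dBA, peak 13:00
    sound_noise_sd: float = 2.0         # dBA white noise
    sound_slow_sd: float = 1.5          # dBA slow drift, ~30-min correlation
    sound_burst_rate: float = 0.01      # events per second per sensor
    sound_burst_amp: float = 8.0        # mean burst height, dBA (exponential)
    # temperature: thermostat-controlled, small diurnal, hour-scale drift
    temp_setpoint: float = 22.0         # °C
    temp_room_sd: float = 0.25          # per-room offset SD
    temp_diurnal_amp: float = 0.2       # °C, peak mid-afternoon
    temp_noise_sd: float = 0.3          # °C, slowly varying noise

    # -- location process --------------------------------------------------
    off_map_fraction: float = 0.15      # target long-run fraction off map
    off_map_dwell_min: float = 10.0     # mean off-map dwell, minutes
    #: mean dwell (minutes) by room group, semi-Markov sojourns; residents
    #: sit for long stretches, so most 21-min windows lie in a single room
    dwell_min: dict[str, float] = Field(
        default_factory=lambda: {
            "living room": 60.0,
            "dining room": 35.0,
            "hallway": 8.0,
            "patient room": 90.0,
            "other": 50.0,
        }
    )
    #: visit probability by destination kind; "home" is the patient's own room
    visit_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "home": 0.30,
            "living room": 0.22,
            "dining room": 0.16,
            "hallway": 0.14,
            "other": 0.18,
        }
    )

    # -- outcome generation ------------------------------------------------
    motor: OutcomeParams = Field(default_factory=_default_motor)
    verbal: OutcomeParams = Field(default_factory=_default_verbal)
    #: per-survey motor→verbal coupling (log-odds added to the verbal channel
    #: when motor agitation is present); co-occurrence beyond the shared
    #: random intercept
    kappa: float = 0.5
    sigma_b: float = 1.0                # SD of the patient random intercept
    #: marginal probability of a resistance-to-care / aggression score ≥ 1
    #: (creates the "agitated but neither motor nor verbal" surveys)
    p_other: float = 0.01
    #: optional targeted-recovery mode: generate *overall* agitation directly
    #: from this logistic model (motor/verbal zeroed, presence expressed as a
    #: resistance-to-care score) so a coefficient can be planted on the
    #: derived agitation outcome itself
    direct_agitation: OutcomeParams | None = None
    #: optional self-initiated (nurse-triggered) extra surveys: expected extra
    #: prompts per patient-day, triggered preferentially at high latent risk
    extra_ema_rate: float = 0.0

    seed: int = 0

    # -- validation --------------------------------------------------------
    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not (self.causal_start_offset > self.causal_end_offset >= 0):
            raise ValueError("causal window requires start_offset > end_offset >= 0")
        if self.sample_period <= 0 or SMOOTHING_SPAN_S % self.sample_period:
            raise ValueError(
                f"sample_period must divide the {SMOOTHING_SPAN_S}-s smoothing span"
            )
        for name in ("light_noise_sd", "sound_noise_sd", "temp_noise_sd",
                     "temp_room_sd", "sigma_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.off_map_fraction < 1:
            raise ValueError("off_map_fraction must be in [0, 1)")
        w0, w1 = self.prompt_window
        if not (0 <= w0 < w1 <= 24):
            raise ValueError("prompt_window must satisfy 0 <= start < end <= 24")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        return self

    # -- derived quantities ------------------------------------------------
    @property
    def causal_buffer_min(self) -> float:
        """Buffer between window end and survey (minutes)."""
        return self.causal_end_offset

    @property
    def causal_length_min(self) -> float:
        """Length of the causal window (minutes)."""
        return self.causal_start_offset - self.causal_end_offset

    @property
    def study_span_s(self) -> int:
        return self.days_per_patient * 86400
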