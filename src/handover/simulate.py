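"""Physics-motivated generator of dyadic handover trials with exact ground truth.

Each trial is built from a small mechanical model of the grasp-lift-transport-
transfer sequence:

* After the giver's fingers touch the object (a minimum-jerk reach ends at
  ``t_contact``), grip force rises as the integral of a bell-shaped (Hann)
  rate pulse whose peak is the giver's anticipatory peak grip force rate —
  drawn from a size-dependent distribution, deliberately independent of
  weight (the giver cannot know the weight before lift-off).
* The vertical load force ramps up linearly at rate ``load_force_rate``
  starting ``contact_latency`` after contact; the object truly lifts off when
  the load first reaches ``m*g``. The true lift delay is therefore
  ``contact_latency + m*g/load_force_rate`` — heavier objects lift later.
* Just after lift-off the net upward force is the continuing ramp, so the
  vertical position follows the integrated kinematics
  ``z(tau) = r_L * tau^3 / (6 m)``; the 2 mm displacement criterion used by
  the analysis pipeline then lags true lift-off by exactly
  ``(6 m d / r_L)^(1/3)``.
* Transport is a horizontal minimum-jerk move of ``transport_distance`` whose
  peak speed is drawn around a weight-dependent target (heavier -> slower);
  minimum-jerk peak speed is 1.875 * distance / duration. The wrist midpoint
  co-moves rigidly with the object while the giver holds it.
* At arrival the receiver grasps: their grip force rises with a Hann rate
  pulse whose peak is drawn from a *weight*-dependent distribution (the
  receiver anticipates weight from the observed kinematics). After a short
  hold the giver's force decays linearly to zero — the end of the handover.
* Each actor's force additionally carries a small, fast contact transient
  (finger-pad compression at touch). Its rate stays below the 30 N/s peak
  threshold, but it makes the 0.07/0.09 N contact criteria fire within one
  sample of true contact, as physical contact does.

Gaussian sensor noise is added per sample to every channel. All drawn values
and exact event times are returned as :class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np

from handover.schedule import (
    Size,
    Weight,
    TrialCondition,
    ExperimentSchedule,
    make_schedule,
    participant_ids,
)
from handover.trial_io import TrialMetadata, TrialRecording

__all__ = [
    "GRAVITY",
    "SimulatorConfig",
    "GroundTruth",
    "ParticipantEffects",
    "UnliftableObjectError",
    "SimulationError",
    "simulate_trial",
    "simulate_experiment",
]

GRAVITY = 9.81  # m/s^2


class SimulationError(RuntimeError):
    """A trial could not be generated under the given configuration."""


class UnliftableObjectError(SimulationError):
    """Grip-force plateau too low to support the object's weight."""


@dataclass(frozen=True)
class SimulatorConfig:
    """Generative parameters of the handover simulator.

    Defaults are calibrated so that the pipeline-detected condition means
    land on typical empirical values for seated tabletop handovers with
    400/700/1000 g objects: lift delays around 249/311/383 ms
    for 400/700/1000 g, peak transport speeds 0.47/0.44/0.42 m/s, receiver
    peak grip force rates 78/85/89 N/s, and giver peak grip force rates that
    depend on object size (pooled mean ~104 N/s) but not weight.
    """

    fs: float = 100.0                     # Hz
    trial_duration: float = 5.0           # s
    gravity: float = GRAVITY              # m/s^2

    # Grasp-to-lift timing.
    contact_latency: float = 0.125        # s between contact and load onset
    contact_latency_sd: float = 0.030     # per-trial jitter, s
    contact_latency_participant_sd: float = 0.030  # per-participant offset, s
    load_force_rate: float = 50.0         # N/s, constant load ramp
    load_force_rate_rel_sd: float = 0.10  # per-trial multiplicative jitter

    # Anticipatory grip-force rate pulses (Hann), peaks in N/s.
    giver_pgfr_mean: dict = field(
        default_factory=lambda: {Size.SMALL: 96.0, Size.BIG: 112.0}
    )
    giver_pgfr_sd: float = 30.0            # per-trial draw sd
    giver_pgfr_participant_sd: float = 45.0
    receiver_pgfr_mean: dict = field(
        default_factory=lambda: {
            Weight.LIGHT: 78.0,
            Weight.MEDIUM: 85.0,
            Weight.HEAVY: 89.0,
        }
    )
    receiver_pgfr_sd: float = 25.0
    receiver_pgfr_participant_sd: float = 35.0
    pgfr_min: float = 40.0                # truncation keeping peaks supra-threshold
    grip_pulse_duration: float = 0.35     # s; force plateau = peak * duration / 2
    grip_pulse_max_duration: float = 1.0  # s; cap on the adaptive extension
    grip_safety_margin: float = 1.2       # plateau must reach margin * m * g

    # Contact transient (finger-pad compression).
    contact_transient_force: float = 0.2  # N
    contact_transient_duration: float = 0.02  # s

    # Transport.
    transport_distance: float = 0.40      # m
    peak_speed: dict = field(
        default_factory=lambda: {
            Weight.LIGHT: 0.47,
            Weight.MEDIUM: 0.44,
            Weight.HEAVY: 0.42,
        }
    )
    peak_speed_sd: float = 0.04           # per-trial draw sd, m/s
    peak_speed_participant_sd: float = 0.05
    peak_speed_min: float = 0.32          # truncation, m/s
    pre_lift_height: float = 0.006        # m of ballistic vertical rise
    settle_duration: float = 0.10         # s to come to vertical rest

    # Reach and transfer timing.
    reach_time_mean: float = 0.50         # s
    reach_time_sd: float = 0.05
    hold_duration: float = 0.25           # s receiver+giver co-hold
    release_duration: float = 0.25        # s linear giver force decay

    # Sensor noise.
    force_noise_sd: float = 0.01          # N
    position_noise_sd: float = 0.2        # mm

    def __post_init__(self) -> None:
        positive = [
            "fs",
            "trial_duration",
            "contact_latency",
            "load_force_rate",
            "grip_pulse_duration",
            "contact_transient_duration",
            "transport_distance",
            "pre_lift_height",
            "settle_duration",
            "hold_duration",
            "release_duration",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "contact_latency_sd",
            "contact_latency_participant_sd",
            "load_force_rate_rel_sd",
            "giver_pgfr_sd",
            "giver_pgfr_participant_sd",
            "receiver_pgfr_sd",
            "receiver_pgfr_participant_sd",
            "peak_speed_sd",
            "peak_speed_participant_sd",
            "reach_time_sd",
            "force_noise_sd",
            "position_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v <= 0 for v in self.giver_pgfr_mean.values()):
            raise ValueError("giver_pgfr_mean values must be strictly positive")
        if any(v <= 0 for v in self.receiver_pgfr_mean.values()):
            raise ValueError("receiver_pgfr_mean values must be strictly positive")
        if any(v <= 0 for v in self.peak_speed.values()):
            raise ValueError("peak_speed values must be strictly positive")

    def noise_free(self) -> "SimulatorConfig":
        """A copy with all noise and trial-to-trial variability switched off."""
        return replace(
            self,
            contact_latency_sd=0.0,
            contact_latency_participant_sd=0.0,
            load_force_rate_rel_sd=0.0,
            giver_pgfr_sd=0.0,
            giver_pgfr_participant_sd=0.0,
            receiver_pgfr_sd=0.0,
            receiver_pgfr_participant_sd=0.0,
            peak_speed_sd=0.0,
            peak_speed_participant_sd=0.0,
            reach_time_sd=0.0,
            force_noise_sd=0.0,
            position_noise_sd=0.0,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["giver_pgfr_mean"] = {k.value: v for k, v in self.giver_pgfr_mean.items()}
        d["receiver_pgfr_mean"] = {
            k.value: v for k, v in self.receiver_pgfr_mean.items()
        }
        d["peak_speed"] = {k.value: v for k, v in self.peak_speed.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorConfig":
        d = dict(d)
        if "giver_pgfr_mean" in d:
            d["giver_pgfr_mean"] = {
                Size(k): float(v) for k, v in d["giver_pgfr_mean"].items()
            }
        if "receiver_pgfr_mean" in d:
            d["receiver_pgfr_mean"] = {
                Weight(k): float(v) for k, v in d["receiver_pgfr_mean"].items()
            }
        if "peak_speed" in d:
            d["peak_speed"] = {Weight(k): float(v) for k, v in d["peak_speed"].items()}
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Exact event times and drawn parameter values used for one trial."""

    t_contact_giver: float     # s, event A
    t_liftoff_true: float      # s, load force first reaches m*g
    t_contact_receiver: float  # s, event C
    t_release_giver: float     # s, event D (giver force back to zero)
    true_lift_delay: float     # s, t_liftoff_true - t_contact_giver
    true_peak_speed: float     # m/s, minimum-jerk transport peak
    true_giver_pgfr: float     # N/s, drawn giver rate-pulse peak
    true_receiver_pgfr: float  # N/s, drawn receiver rate-pulse peak
    mass_kg: float
    load_force_rate: float     # N/s, after per-trial jitter
    contact_latency: float     # s, after offsets/jitter

    def __post_init__(self) -> None:
        times = (
            self.t_contact_giver,
            self.t_liftoff_true,
            self.t_contact_receiver,
            self.t_release_giver,
        )
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times must be strictly increasing: {times}")
        if self.true_lift_delay <= 0:
            raise ValueError("true_lift_delay must be positive")


@dataclass(frozen=True)
class ParticipantEffects:
    """Stable per-participant offsets, constant across that person's trials."""

    giver_pgfr_offset: float = 0.0      # N/s
    receiver_pgfr_offset: float = 0.0   # N/s
    contact_latency_offset: float = 0.0  # s
    peak_speed_offset: float = 0.0      # m/s

    @classmethod
    def draw(cls, config: SimulatorConfig, rng: np.random.Generator) -> "ParticipantEffects":
        return cls(
            giver_pgfr_offset=rng.normal(0.0, config.giver_pgfr_participant_sd),
            receiver_pgfr_offset=rng.normal(0.0, config.receiver_pgfr_participant_sd),
            contact_latency_offset=rng.normal(
                0.0, config.contact_latency_participant_sd
            ),
            peak_speed_offset=rng.normal(0.0, config.peak_speed_participant_sd),
        )


def _hann_pulse_integral(tau: np.ndarray, peak: float, duration: float) -> np.ndarray:
    """Integral of the Hann rate pulse ``peak/2 * (1 - cos(2*pi*tau/T))``.

    Rises smoothly from 0 to the plateau ``peak * duration / 2``.
    """
    t = np.clip(tau, 0.0, duration)
    return 0.5 * peak * (t - duration / (2.0 * math.pi) * np.sin(2.0 * math.pi * t / duration))


def _transient_step(tau: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    """Fast half-cosine step from 0 to ``amplitude`` over ``duration``."""
    t = np.clip(tau, 0.0, duration)
    return 0.5 * amplitude * (1.0 - np.cos(math.pi * t / duration))


def _min_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on normalized time s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


def simulate_trial(
    cond: TrialCondition,
    config: SimulatorConfig,
    rng: np.random.Generator | int | None = None,
    giver_effects: ParticipantEffects | None = None,
    receiver_effects: ParticipantEffects | None = None,
    mass_kg: float | None = None,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one handover trial and its exact ground truth.

    Parameters
    ----------
    cond:
        Trial condition (dyad, block, size, weight, actor ids).
    config:
        Generative parameters; see :class:`SimulatorConfig`.
    rng:
        numpy Generator or seed for all of this trial's draws and noise.
    giver_effects, receiver_effects:
        Optional stable per-participant offsets (drawn by
        :func:`simulate_experiment`); zero offsets when omitted.
    mass_kg:
        Override the condition's object mass (sensitivity studies, e.g. the
        light-mass limit); defaults to the condition's weight.
    """
    rng = np.random.default_rng(rng)
    ge = giver_effects or ParticipantEffects()
    re = receiver_effects or ParticipantEffects()
    m = cond.mass_kg if mass_kg is None else float(mass_kg)
    if m <= 0:
        raise ValueError("object mass must be strictly positive")
    g = config.gravity

    # --- per-trial parameter draws -------------------------------------
    reach_time = max(
        0.2, rng.normal(config.reach_time_mean, config.reach_time_sd)
    )
    t_lat = max(
        0.02,
        config.contact_latency
        + ge.contact_latency_offset
        + rng.normal(0.0, config.contact_latency_sd),
    )
    r_load = max(
        10.0,
        config.load_force_rate
        * (1.0 + rng.normal(0.0, config.load_force_rate_rel_sd)),
    )
    giver_pgfr = max(
        config.pgfr_min,
        rng.normal(config.giver_pgfr_mean[cond.size], config.giver_pgfr_sd)
        + ge.giver_pgfr_offset,
    )
    receiver_pgfr = max(
        config.pgfr_min,
        rng.normal(config.receiver_pgfr_mean[cond.weight], config.receiver_pgfr_sd)
        + re.receiver_pgfr_offset,
    )
    v_peak = max(
        config.peak_speed_min,
        rng.normal(config.peak_speed[cond.weight], config.peak_speed_sd)
        + ge.peak_speed_offset,
    )

    # The grip-force plateau (peak * pulse_duration / 2 + transient) must hold
    # a safety margin over the object's weight. An actor producing a lower
    # rate takes longer to build up force, so the pulse duration extends as
    # needed — up to a cap, beyond which the object counts as unliftable.
    def _pulse_duration(peak: float) -> float:
        required = config.grip_safety_margin * m * g - config.contact_transient_force
        duration = max(config.grip_pulse_duration, 2.0 * required / peak)
        if duration > config.grip_pulse_max_duration:
            plateau = (
                peak * config.grip_pulse_max_duration / 2.0
                + config.contact_transient_force
            )
            raise UnliftableObjectError(
                f"grip-force plateau {plateau:.2f} N cannot support "
                f"{config.grip_safety_margin:.2f} x {m * g:.2f} N object weight"
            )
        return duration

    giver_pulse_T = _pulse_duration(giver_pgfr)
    receiver_pulse_T = _pulse_duration(receiver_pgfr)

    # --- event timeline (continuous) -----------------------------------
    t_contact = 0.3 + reach_time
    t_liftoff = t_contact + t_lat + m * g / r_load
    tau_rise = (6.0 * m * config.pre_lift_height / r_load) ** (1.0 / 3.0)
    v1 = r_load * tau_rise**2 / (2.0 * m)  # vertical speed at end of ballistic rise
    t_transport = t_liftoff + tau_rise + config.settle_duration
    transport_T = 1.875 * config.transport_distance / v_peak
    t_contact_recv = t_transport + transport_T
    # giver keeps hold at least until the receiver's rate peak has passed
    hold = max(config.hold_duration, receiver_pulse_T / 2.0 + 0.05)
    t_release_start = t_contact_recv + hold
    t_release = t_release_start + config.release_duration

    if t_release + 0.3 > config.trial_duration:
        raise SimulationError(
            f"trial timeline ({t_release + 0.3:.2f} s) exceeds trial_duration "
            f"{config.trial_duration} s; increase trial_duration"
        )

    n = int(round(config.trial_duration * config.fs))
    t = np.arange(n) / config.fs

    # --- giver grip force ----------------------------------------------
    base = _transient_step(
        t - t_contact, config.contact_transient_force, config.contact_transient_duration
    ) + _hann_pulse_integral(t - t_contact, giver_pgfr, giver_pulse_T)
    decay = np.clip((t - t_release_start) / config.release_duration, 0.0, 1.0)
    giver_force = base * (1.0 - decay)

    # --- receiver grip force -------------------------------------------
    receiver_force = _transient_step(
        t - t_contact_recv,
        config.contact_transient_force,
        config.contact_transient_duration,
    ) + _hann_pulse_integral(t - t_contact_recv, receiver_pgfr, receiver_pulse_T)

    # --- object kinematics (m; converted to mm below) -------------------
    z0 = 0.05
    z = np.full(n, z0)
    tau = t - t_liftoff
    rise = (tau > 0) & (tau <= tau_rise)
    z[rise] = z0 + r_load * tau[rise] ** 3 / (6.0 * m)
    z1 = z0 + config.pre_lift_height
    s = (tau - tau_rise) / config.settle_duration
    settle = (s > 0) & (s <= 1)
    # velocity v1*(1+cos(pi*s))/2 integrates to this; ends at vertical rest
    z[settle] = z1 + 0.5 * v1 * config.settle_duration * (
        s[settle] + np.sin(math.pi * s[settle]) / math.pi
    )
    z_lift = z1 + 0.5 * v1 * config.settle_duration
    z[tau > tau_rise + config.settle_duration] = z_lift

    x = config.transport_distance * _min_jerk((t - t_transport) / transport_T)
    y = np.zeros(n)
    object_pos = np.column_stack([x, y, z])

    # --- giver wrist ----------------------------------------------------
    grasp_offset = np.array([0.0, 0.0, -0.02])
    wrist_start = object_pos[0] + grasp_offset + np.array([-0.25, 0.0, 0.05])
    grasp_point = object_pos[0] + grasp_offset
    mid = np.empty((n, 3))
    pre = t <= t_contact
    s_reach = (t[pre] - (t_contact - reach_time)) / reach_time
    mid[pre] = wrist_start + np.outer(_min_jerk(s_reach), grasp_point - wrist_start)
    holding = (t > t_contact) & (t <= t_release)
    mid[holding] = object_pos[holding] + grasp_offset
    after = t > t_release
    release_idx = np.searchsorted(t, t_release)
    anchor = object_pos[min(release_idx, n - 1)] + grasp_offset
    mid[after] = anchor

    lateral = np.array([0.0, 0.01, 0.0])
    radius = mid + lateral
    ulna = mid - lateral

    # --- units and noise -------------------------------------------------
    object_mm = object_pos * 1000.0
    radius_mm = radius * 1000.0
    ulna_mm = ulna * 1000.0
    if config.force_noise_sd > 0:
        giver_force = giver_force + rng.normal(0.0, config.force_noise_sd, n)
        receiver_force = receiver_force + rng.normal(0.0, config.force_noise_sd, n)
    if config.position_noise_sd > 0:
        object_mm = object_mm + rng.normal(0.0, config.position_noise_sd, (n, 3))
        radius_mm = radius_mm + rng.normal(0.0, config.position_noise_sd, (n, 3))
        ulna_mm = ulna_mm + rng.normal(0.0, config.position_noise_sd, (n, 3))

    rec = TrialRecording(
        time=t,
        giver_force=giver_force,
        receiver_force=receiver_force,
        object_pos=object_mm,
        radius_marker=radius_mm,
        ulna_marker=ulna_mm,
        meta=TrialMetadata(condition=cond, fs=config.fs),
    )
    gt = GroundTruth(
        t_contact_giver=t_contact,
        t_liftoff_true=t_liftoff,
        t_contact_receiver=t_contact_recv,
        t_release_giver=t_release,
        true_lift_delay=t_liftoff - t_contact,
        true_peak_speed=v_peak,
        true_giver_pgfr=giver_pgfr,
        true_receiver_pgfr=receiver_pgfr,
        mass_kg=m,
        load_force_rate=r_load,
        contact_latency=t_lat,
    )
    return rec, gt


def _substream(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, keys))))


def simulate_experiment(
    n_dyads: int,
    config: SimulatorConfig | None = None,
    seed: int = 0,
) -> Iterator[tuple[TrialRecording, GroundTruth]]:
    """Generate all trials of an ``n_dyads``-dyad experiment, lazily.

    Each dyad follows its own 120-trial schedule; the size block order is
    counterbalanced by alternating across dyads. One master seed drives
    everything: per-trial substreams are derived from (dyad, block, trial)
    and participant offsets from (dyad,), so any single trial is reproducible
    in isolation. Errors raised by :func:`simulate_trial` are re-raised with
    the offending trial identified.
    """
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    if config is None:
        config = SimulatorConfig()
    for d in range(n_dyads):
        dyad_id = f"D{d + 1:02d}"
        schedule = make_schedule(
            dyad_id, counterbalance_flag=bool(d % 2), seed=int(seed) * 1009 + d
        )
        p_a, p_b = participant_ids(dyad_id)
        eff_rng = _substream(seed, 1, d)
        effects = {
            p_a: ParticipantEffects.draw(config, eff_rng),
            p_b: ParticipantEffects.draw(config, eff_rng),
        }
        for cond in schedule:
            rng = _substream(seed, 2, d, cond.block, cond.trial_in_block)
            try:
                yield simulate_trial(
                    cond,
                    config,
                    rng,
                    giver_effects=effects[cond.giver_id],
                    receiver_effects=effects[cond.receiver_id],
                )
            except SimulationError as err:
                raise SimulationError(
                    f"dyad {dyad_id} block {cond.block} trial "
                    f"{cond.trial_in_block}: {err}"
                ) from err
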