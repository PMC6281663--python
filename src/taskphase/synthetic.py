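"""Synthetic spike-train generator for the binocular-flash-suppression (BFS) task.

The generator emulates the statistical structure the downstream analysis
assumes: a population of *phase-tuned* units whose firing-rate profiles peak
in distinct phases of the 2000 ms trial (identically across the four stimulus
conditions), *stimulus-selective* units whose rate follows the perceptually
dominant stimulus, low-rate *junk* units, and trial-to-trial shared-gain
fluctuations whose pairwise correlation decays with the temporal distance
between the units' phase tuning and is weak across the phase-tuned /
stimulus-selective population boundary.

Trial layout (times in ms relative to first-stimulus onset): the first
stimulus is shown monocularly during [0, 1000); at 1000 ms the second
stimulus appears — in physical-alternation (PA) trials the first is removed,
in flash-suppression (FS) trials it stays on but is perceptually suppressed.
Perceptual dominance is therefore deterministic: first stimulus dominates
the first half, second stimulus the second half, in both trial types.

Every generated unit has a ground-truth record, so each downstream stage can
be tested against planted structure without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

#: canonical condition order: (a) FS polar-first, (b) PA polar-first,
#: (c) FS face-first, (d) PA face-first
CONDITIONS = ("FS_polar_first", "PA_polar_first", "FS_face_first", "PA_face_first")

#: inclusive 0..2000 ms grid, 8 ms step -> 251 samples per condition
GRID_MS = np.arange(0.0, 2000.0 + 4.0, 8.0)
N_SAMPLES = 251
TRIAL_MS = 2000.0
SWITCH_MS = 1000.0

UNIT_CLASSES = ("phase_tuned", "stimulus_selective", "junk")


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Rates are in spikes/s.  Phase-tuned units are heterogeneous within a
    template: each unit's template is shifted by a draw from
    ``N(0, peak_jitter_sd_ms)`` and its whole profile scaled by a log-normal
    amplitude with log-SD ``amplitude_sd`` (real populations tile a task
    phase rather than repeating one profile).  ``coupling_same_group`` is
    the latent-gain correlation for two units sharing a template (or a
    stimulus preference); between phase groups it decays as
    ``coupling_decay ** temporal_distance``; ``coupling_cross_population``
    is the latent correlation for phase-tuned vs stimulus-selective pairs.
    Gains are multiplicative log-normal with unit mean and log-scale
    ``gain_sd``.
    """

    n_sessions: int = 1
    phase_tuned_per_template: int = 20
    n_stimulus_selective: int = 10
    n_junk: int = 5
    trials_per_condition: int = 20
    template_ids: tuple[int, ...] = (0, 1, 2, 3, 4)
    baseline_rate: float = 2.0
    peak_rate: float = 10.0
    junk_rate: float = 0.2
    peak_jitter_sd_ms: float = 60.0
    amplitude_sd: float = 0.4
    gain_sd: float = 0.3
    coupling_same_group: float = 0.3
    coupling_decay: float = 0.5
    coupling_cross_population: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_rate", "peak_rate", "junk_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.trials_per_condition < 2:
            raise ConfigurationError("trials_per_condition must be >= 2")
        if not 0.0 <= self.coupling_same_group <= 1.0:
            raise ConfigurationError("coupling_same_group must be in [0, 1]")
        if not 0.0 <= self.coupling_decay <= 1.0:
            raise ConfigurationError("coupling_decay must be in [0, 1]")
        if abs(self.coupling_cross_population) > self.coupling_same_group:
            raise ConfigurationError(
                "coupling_cross_population exceeds coupling_same_group; the "
                "latent-gain covariance would not be positive semi-definite"
            )
        if any(t not in range(5) for t in self.template_ids):
            raise ConfigurationError("template_ids must index the 5-template library")
        if self.gain_sd < 0:
            raise ConfigurationError("gain_sd must be >= 0")
        if self.peak_jitter_sd_ms < 0 or self.amplitude_sd < 0:
            raise ConfigurationError("heterogeneity SDs must be >= 0")


@dataclass(frozen=True)
class TemplateSet:
    """Library of unit-peak canonical rate profiles over the condition grid."""

    grid: np.ndarray
    profiles: np.ndarray  # (n_templates, 251), each max exactly 1
    peak_times_ms: np.ndarray  # strictly increasing

    def __len__(self) -> int:
        return self.profiles.shape[0]


@dataclass
class GroundTruth:
    """Per-unit planted structure: class, template / preferred stimulus, session."""

    units: pd.DataFrame  # unit_id, session_id, unit_class, template_id, pref_stimulus
    config: SyntheticConfig

    def planted_latent_correlation(self, unit_a: str, unit_b: str) -> float:
        """Correlation of the latent trial gains planted for a unit pair."""
        info = self.units.set_index("unit_id")
        a, b = info.loc[unit_a], info.loc[unit_b]
        if a["session_id"] != b["session_id"] or unit_a == unit_b:
            raise ValueError("planted correlations are defined for distinct same-session units")
        return _planted_correlation(a, b, self.config)


def _planted_correlation(a: pd.Series, b: pd.Series, cfg: SyntheticConfig) -> float:
    s2 = cfg.coupling_same_group
    ca, cb = a["unit_class"], b["unit_class"]
    if "junk" in (ca, cb):
        return 0.0
    if ca == "phase_tuned" and cb == "phase_tuned":
        d = abs(int(a["template_id"]) - int(b["template_id"]))
        return s2 * cfg.coupling_decay**d
    if ca == "stimulus_selective" and cb == "stimulus_selective":
        return s2 if a["pref_stimulus"] == b["pref_stimulus"] else 0.0
    return cfg.coupling_cross_population


# ---------------------------------------------------------------------------
# template library
# ---------------------------------------------------------------------------

_BUMP_SD_MS = 150.0
# Gaussian bump centers for the four non-ramp phases (trial start,
# post-first-stimulus, post-second-stimulus, trial end); the middle template
# is a linear ramp to the expected 1000 ms stimulus switch with a Gaussian
# fall-off after it.
_BUMP_CENTERS_MS = (80.0, 540.0, 1460.0, 1920.0)


def make_template_library(grid: np.ndarray = GRID_MS) -> TemplateSet:
    """Build the five canonical phase templates on the condition grid.

    Deterministic.  Raises :class:`ConfigurationError` if ``grid`` is not the
    canonical 0–2000 ms / 8 ms convention (251 inclusive samples).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (N_SAMPLES,) or not np.allclose(grid, GRID_MS):
        raise ConfigurationError("grid must be the canonical 0..2000 ms, 8 ms step grid")

    def bump(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((grid - center) / _BUMP_SD_MS) ** 2)

    ramp = np.where(
        grid <= SWITCH_MS,
        grid / SWITCH_MS,
        np.exp(-0.5 * ((grid - SWITCH_MS) / _BUMP_SD_MS) ** 2),
    )
    profiles = np.stack(
        [bump(_BUMP_CENTERS_MS[0]), bump(_BUMP_CENTERS_MS[1]), ramp,
         bump(_BUMP_CENTERS_MS[2]), bump(_BUMP_CENTERS_MS[3])]
    )
    profiles /= profiles.max(axis=1, keepdims=True)
    peaks = grid[np.argmax(profiles, axis=1)]
    if not np.all(np.diff(peaks) > 0):  # pragma: no cover - construction guarantee
        raise ConfigurationError("template peak times must be strictly increasing")
    return TemplateSet(grid=grid, profiles=profiles, peak_times_ms=peaks)


# ---------------------------------------------------------------------------
# spike sampling
# ---------------------------------------------------------------------------

def sample_inhomogeneous_poisson(
    rate_profile: np.ndarray,
    gain: float = 1.0,
    grid: np.ndarray = GRID_MS,
    *,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample spike times (ms) from an inhomogeneous Poisson process.

    ``rate_profile`` is in spikes/s on ``grid`` (ms); the effective intensity
    is ``gain * rate_profile``.  Sampling is by inversion of the cumulative
    intensity, so the spike count is exactly Poisson with mean
    ``gain * integral(rate) dt``.
    """
    rate = np.asarray(rate_profile, dtype=float)
    if rate.shape != grid.shape:
        raise ValueError("rate_profile and grid must have matching shapes")
    if np.any(rate < 0):
        raise ValueError("rate_profile must be non-negative")
    if gain <= 0:
        raise ValueError("gain must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    cum = gain * cumulative_trapezoid(rate / 1000.0, grid, initial=0.0)  # spikes
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    n = rng.poisson(total)
    if n == 0:
        return np.empty(0)
    u = np.sort(rng.uniform(0.0, total, size=n))
    return np.interp(u, cum, grid)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def _group_correlation_matrix(cfg: SyntheticConfig) -> tuple[np.ndarray, dict[str, int]]:
    """Latent-factor correlation matrix across groups.

    One factor per phase template (Kac–Murdock–Szegő decay between them), one
    per stimulus preference.  Unit latents mix their group factor with weight
    sqrt(coupling_same_group), giving the configured pairwise correlations.
    """
    n_phase = len(cfg.template_ids)
    groups = {f"tpl{t}": i for i, t in enumerate(cfg.template_ids)}
    groups["polar"] = n_phase
    groups["face"] = n_phase + 1
    G = np.eye(n_phase + 2)
    for i, ti in enumerate(cfg.template_ids):
        for j, tj in enumerate(cfg.template_ids):
            if i != j:
                G[i, j] = cfg.coupling_decay ** abs(ti - tj)
    if cfg.coupling_same_group > 0:
        cross = cfg.coupling_cross_population / cfg.coupling_same_group
        G[:n_phase, n_phase:] = cross
        G[n_phase:, :n_phase] = cross
    elif cfg.coupling_cross_population != 0:
        raise ConfigurationError(
            "coupling_cross_population requires coupling_same_group > 0"
        )
    w = np.linalg.eigvalsh(G)
    if w.min() < -1e-10:
        raise ConfigurationError(
            "coupling_decay / coupling_cross_population combination yields a "
            "non-positive-semi-definite latent-gain covariance"
        )
    return G, groups


def _phase_profile(cfg: SyntheticConfig, templates: TemplateSet,
                   template_id: int, shift_ms: float, amplitude: float) -> np.ndarray:
    shifted = np.interp(GRID_MS - shift_ms, GRID_MS, templates.profiles[template_id])
    return amplitude * (cfg.baseline_rate
                        + (cfg.peak_rate - cfg.baseline_rate) * shifted)


def _selective_profile(cfg: SyntheticConfig, pref: str, cond: str,
                       amplitude: float) -> np.ndarray:
    first_stim = "polar" if "polar_first" in cond else "face"
    dominant = (GRID_MS < SWITCH_MS) if pref == first_stim else (GRID_MS >= SWITCH_MS)
    return amplitude * (cfg.baseline_rate
                        + (cfg.peak_rate - cfg.baseline_rate) * dominant.astype(float))


def unit_rate_profile(unit: pd.Series, cfg: SyntheticConfig,
                      templates: TemplateSet | None = None) -> dict[str, np.ndarray]:
    """Expected rate profile (spikes/s) of a ground-truth unit per condition."""
    templates = templates or make_template_library()
    if unit["unit_class"] == "phase_tuned":
        p = _phase_profile(cfg, templates, int(unit["template_id"]),
                           float(unit["peak_shift_ms"]), float(unit["amplitude"]))
        return {c: p for c in CONDITIONS}
    if unit["unit_class"] == "stimulus_selective":
        return {c: _selective_profile(cfg, unit["pref_stimulus"], c,
                                      float(unit["amplitude"]))
                for c in CONDITIONS}
    return {c: np.full(N_SAMPLES, cfg.junk_rate) for c in CONDITIONS}


def sample_population(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a multi-session population of spike trains with ground truth.

    Returns a long-format spike table (one row per spike: session_id, unit_id,
    condition_code, trial_index, spike_time_ms) and the :class:`GroundTruth`.
    All units of one session share trial indices and the per-trial latent
    gain draws (simultaneous recording).
    """
    config.validate()
    templates = make_template_library()
    G, group_index = _group_correlation_matrix(config)
    evals, evecs = np.linalg.eigh(G)
    G_sqrt = evecs * np.sqrt(np.clip(evals, 0.0, None))
    s = np.sqrt(config.coupling_same_group)

    ss = np.random.SeedSequence(config.seed)
    session_seeds = ss.spawn(config.n_sessions)

    unit_rows: list[dict] = []
    spike_frames: list[pd.DataFrame] = []
    for sidx in range(config.n_sessions):
        rng = np.random.default_rng(session_seeds[sidx])
        session_id = f"s{sidx:02d}"
        units: list[dict] = []
        u = 0
        for t in config.template_ids:
            for _ in range(config.phase_tuned_per_template):
                units.append({"unit_id": f"{session_id}_u{u:04d}",
                              "unit_class": "phase_tuned", "template_id": t,
                              "pref_stimulus": "",
                              "peak_shift_ms": rng.normal(0.0, config.peak_jitter_sd_ms),
                              "amplitude": np.exp(rng.normal(0.0, config.amplitude_sd))})
                u += 1
        for k in range(config.n_stimulus_selective):
            units.append({"unit_id": f"{session_id}_u{u:04d}",
                          "unit_class": "stimulus_selective", "template_id": -1,
                          "pref_stimulus": "polar" if k % 2 == 0 else "face",
                          "peak_shift_ms": 0.0,
                          "amplitude": np.exp(rng.normal(0.0, config.amplitude_sd))})
            u += 1
        for _ in range(config.n_junk):
            units.append({"unit_id": f"{session_id}_u{u:04d}", "unit_class": "junk",
                          "template_id": -1, "pref_stimulus": "",
                          "peak_shift_ms": 0.0, "amplitude": 1.0})
            u += 1

        for rec in units:
            unit_rows.append({**rec, "session_id": session_id})

        # per-unit per-condition rate profiles (phase-tuned: condition-invariant)
        profiles = []
        for rec in units:
            if rec["unit_class"] == "phase_tuned":
                p = _phase_profile(config, templates, rec["template_id"],
                                   rec["peak_shift_ms"], rec["amplitude"])
                profiles.append({c: p for c in CONDITIONS})
            elif rec["unit_class"] == "stimulus_selective":
                profiles.append({c: _selective_profile(config, rec["pref_stimulus"],
                                                       c, rec["amplitude"])
                                 for c in CONDITIONS})
            else:
                profiles.append({c: np.full(N_SAMPLES, config.junk_rate)
                                 for c in CONDITIONS})

        n_units = len(units)
        group_of = np.full(n_units, -1)
        for i, rec in enumerate(units):
            if rec["unit_class"] == "phase_tuned":
                group_of[i] = group_index[f"tpl{rec['template_id']}"]
            elif rec["unit_class"] == "stimulus_selective":
                group_of[i] = group_index[rec["pref_stimulus"]]

        recs: dict[str, list] = {k: [] for k in
                                 ("unit_id", "condition_code", "trial_index", "spike_time_ms")}
        for cond in CONDITIONS:
            for trial in range(config.trials_per_condition):
                z = rng.standard_normal(G.shape[0])
                factors = G_sqrt @ z
                eps = rng.standard_normal(n_units)
                latent = np.where(
                    group_of >= 0,
                    s * factors[np.clip(group_of, 0, None)] + np.sqrt(1 - s**2) * eps,
                    eps,
                )
                gains = np.exp(config.gain_sd * latent - 0.5 * config.gain_sd**2)
                for i, rec in enumerate(units):
                    spikes = sample_inhomogeneous_poisson(
                        profiles[i][cond], gains[i], rng=rng)
                    if spikes.size:
                        recs["unit_id"].extend([rec["unit_id"]] * spikes.size)
                        recs["condition_code"].extend([cond] * spikes.size)
                        recs["trial_index"].extend([trial] * spikes.size)
                        recs["spike_time_ms"].extend(spikes.tolist())
        frame = pd.DataFrame(recs)
        frame.insert(0, "session_id", session_id)
        spike_frames.append(frame)

    spikes_df = pd.concat(spike_frames, ignore_index=True)
    truth = GroundTruth(units=pd.DataFrame(unit_rows), config=config)
    return spikes_df, truth


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_spike_table(spikes: pd.DataFrame, path) -> None:
    spikes.to_csv(path, index=False, float_format="%.4f")


def read_spike_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"session_id": str, "unit_id": str, "condition_code": str,
               "trial_index": int, "spike_time_ms": float},
    )


def write_ground_truth(truth: GroundTruth, units_path, config_path=None) -> None:
    truth.units.to_csv(units_path, index=False)
    if config_path is not None:
        import yaml

        with open(config_path, "w") as fh:
            yaml.safe_dump(asdict(truth.config), fh, sort_keys=True)
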