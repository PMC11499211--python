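"""Seeded Markov-chain generator of synthetic maternal-behavior observations.

Each (housing group, phase class) pair has a :class:`PhaseProfile` describing
a discrete-time Markov chain over the 7 scored behavior codes, factored as

    T_d = (1 - f_d) * I + f_d * K

where ``K`` is a row-stochastic *switch kernel* with zero diagonal (the
conditional destination given that the dam switches behavior) and ``f_d`` is
the per-slot switch probability on postpartum day *d*:

    f_d = clip(f + day_drift * (d - 2), 0, 1).

Factoring fragmentation ``f`` out of the kernel makes "more fragmented, same
repertoire" a single-parameter manipulation: the expected number of
behavioral transitions in a 25-slot session is simply ``24 * f_d``.

The default presets emulate the qualitative pattern reported for the
limited-bedding-and-nesting (LBN) manipulation: high crouch (HG) elevated in
LBN dams in both phases, supine nursing suppressed in the LBN light phase,
control dams OFF-dominant in the dark phase, transitions declining across
postpartum days (negative ``day_drift``), and an elevated dark-phase switch
probability for LBN dams.  The specific probabilities and fragmentation
values are tuning choices of this generator, not measured quantities; see
``docs/methods.md``.

Per-dam random streams are derived from the global seed with a stable spawn
key (group index, dam index), so enlarging ``n_dams_per_group`` never
reshuffles the sessions of existing dams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .ethogram import (
    CODES,
    GROUPS,
    PERIODS,
    PPD_MAX,
    PPD_MIN,
    SLOTS_PER_PERIOD,
    Dataset,
    ObservationSession,
)

__all__ = [
    "PhaseProfile",
    "SimConfig",
    "default_profiles",
    "default_config",
    "effective_transition_matrix",
    "simulate_codes",
    "simulate_session",
    "simulate_dataset",
]

PHASE_CLASSES = ("LIGHT", "DARK")
_N = len(CODES)
#: Phase class sampled by each observation period.
PERIOD_PHASE = {"AM": "LIGHT", "PM": "LIGHT", "DARK": "DARK"}


@dataclass(frozen=True)
class PhaseProfile:
    """Markov-chain parameters for one (group, phase-class) condition.

    Parameters
    ----------
    initial_dist : array of shape (7,)
        Distribution of the behavior at slot 0, over :data:`~maternet.ethogram.CODES`.
    switch_kernel : array of shape (7, 7)
        Row-stochastic conditional destination given a switch; zero diagonal.
    fragmentation : float
        Baseline per-slot switch probability ``f`` on PPD 2, in [0, 1].
    day_drift : float
        Additive change of ``f`` per postpartum day (negative = transitions
        decline as the litter matures).
    """

    initial_dist: np.ndarray
    switch_kernel: np.ndarray
    fragmentation: float
    day_drift: float = 0.0

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_dist, dtype=float)
        kernel = np.asarray(self.switch_kernel, dtype=float)
        if init.shape != (_N,):
            raise ValueError(f"initial_dist must have shape ({_N},)")
        if kernel.shape != (_N, _N):
            raise ValueError(f"switch_kernel must have shape ({_N}, {_N})")
        if np.any(init < 0) or not np.isclose(init.sum(), 1.0):
            raise ValueError("initial_dist must be a probability vector")
        if np.any(kernel < 0):
            raise ValueError("switch_kernel entries must be non-negative")
        if np.any(np.diag(kernel) != 0):
            raise ValueError("switch_kernel must have a zero diagonal (no self-switches)")
        if not np.allclose(kernel.sum(axis=1), 1.0):
            raise ValueError("switch_kernel rows must sum to 1")
        if not (0.0 <= self.fragmentation <= 1.0):
            raise ValueError("fragmentation must lie in [0, 1]")
        init = init / init.sum()
        object.__setattr__(self, "initial_dist", init)
        object.__setattr__(self, "switch_kernel", kernel)

    def effective_fragmentation(self, ppd: int) -> float:
        """Per-slot switch probability on postpartum day ``ppd`` (clipped to [0, 1])."""
        return float(np.clip(self.fragmentation + self.day_drift * (ppd - PPD_MIN), 0.0, 1.0))


def effective_transition_matrix(profile: PhaseProfile, ppd: int) -> np.ndarray:
    """Row-stochastic slot-to-slot transition matrix ``(1 - f_d) I + f_d K``."""
    f = profile.effective_fragmentation(ppd)
    return (1.0 - f) * np.eye(_N) + f * profile.switch_kernel


def _attraction_kernel(weights: np.ndarray) -> np.ndarray:
    """Zero-diagonal kernel whose row *i* is ``weights`` renormalized without *i*.

    Destinations are drawn in proportion to how prominent each behavior is in
    the condition overall, which keeps the chain's occupancy close to the
    intended repertoire while remaining a one-vector parameterization.
    """
    w = np.asarray(weights, dtype=float)
    kernel = np.tile(w, (_N, 1))
    np.fill_diagonal(kernel, 0.0)
    return kernel / kernel.sum(axis=1, keepdims=True)


def default_profiles() -> dict[tuple[str, str], PhaseProfile]:
    """The four preset (group, phase-class) profiles used throughout.

    Code order: HG, LW, SUP, L, HG/L, DN, OFF.
    """
    repertoire = {
        # Light phase: dam mostly in the nest nursing; HG dominant.
        ("CTRL", "LIGHT"): [0.40, 0.15, 0.08, 0.02, 0.10, 0.15, 0.10],
        # LBN light: HG boosted, supine suppressed.
        ("LBN", "LIGHT"): [0.50, 0.15, 0.03, 0.02, 0.12, 0.10, 0.08],
        # Control dark: dam mostly off the nest.
        ("CTRL", "DARK"): [0.15, 0.08, 0.04, 0.01, 0.05, 0.22, 0.45],
        # LBN dark: HG boosted, off-nest reduced.
        ("LBN", "DARK"): [0.30, 0.08, 0.04, 0.01, 0.08, 0.25, 0.24],
    }
    # Baseline switch probability per 3-min slot; LBN dark phase is the one
    # condition with elevated fragmentation.  All conditions drift downward
    # across postpartum days.
    frag = {
        ("CTRL", "LIGHT"): 0.35,
        ("LBN", "LIGHT"): 0.35,
        ("CTRL", "DARK"): 0.35,
        ("LBN", "DARK"): 0.50,
    }
    drift = -0.015
    return {
        key: PhaseProfile(
            initial_dist=np.asarray(weights, dtype=float),
            switch_kernel=_attraction_kernel(np.asarray(weights, dtype=float)),
            fragmentation=frag[key],
            day_drift=drift,
        )
        for key, weights in repertoire.items()
    }


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a simulated experiment.

    Defaults reproduce the study design: 9 dams per housing group observed on
    postpartum days 2-9, three periods per day (AM and PM draw from the LIGHT
    profile, DARK from the dark profile).
    """

    n_dams_per_group: int = 9
    ppd_range: tuple[int, int] = (PPD_MIN, PPD_MAX)
    profiles: Mapping[tuple[str, str], PhaseProfile] = field(default_factory=default_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dams_per_group < 1:
            raise ValueError("n_dams_per_group must be >= 1")
        lo, hi = self.ppd_range
        if not (PPD_MIN <= lo <= hi <= PPD_MAX):
            raise ValueError(f"ppd_range must lie within [{PPD_MIN}, {PPD_MAX}]")
        missing = [
            (g, p) for g in GROUPS for p in PHASE_CLASSES if (g, p) not in self.profiles
        ]
        if missing:
            raise ValueError(f"missing profiles for {missing}")

    @property
    def ppds(self) -> range:
        return range(self.ppd_range[0], self.ppd_range[1] + 1)


def default_config(seed: int = 0, n_dams_per_group: int = 9) -> SimConfig:
    return SimConfig(n_dams_per_group=n_dams_per_group, seed=seed)


def load_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML key-value file.

    Recognized top-level keys: ``seed``, ``n_dams_per_group``, ``ppd_min``,
    ``ppd_max`` and one mapping per profile (``ctrl_light``, ``ctrl_dark``,
    ``lbn_light``, ``lbn_dark``) overriding any of ``fragmentation``,
    ``day_drift``, ``initial_dist`` (7 floats) and ``switch_kernel``
    (7x7 rows).  Omitted entries keep the preset values.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    profiles = default_profiles()
    for group in GROUPS:
        for phase in PHASE_CLASSES:
            key = f"{group.lower()}_{phase.lower()}"
            override = raw.pop(key, None)
            if override is None:
                continue
            profile = profiles[(group, phase)]
            fields = {}
            for name in ("fragmentation", "day_drift"):
                if name in override:
                    fields[name] = float(override[name])
            for name in ("initial_dist", "switch_kernel"):
                if name in override:
                    fields[name] = np.asarray(override[name], dtype=float)
            profiles[(group, phase)] = replace(profile, **fields)
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw.pop("seed"))
    if "n_dams_per_group" in raw:
        kwargs["n_dams_per_group"] = int(raw.pop("n_dams_per_group"))
    lo = int(raw.pop("ppd_min", PPD_MIN))
    hi = int(raw.pop("ppd_max", PPD_MAX))
    if raw:
        raise ValueError(f"{path}: unknown config keys {sorted(raw)}")
    return SimConfig(profiles=profiles, ppd_range=(lo, hi), **kwargs)


def _draw_categorical(cdf: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized inverse-CDF draw.  ``cdf`` is (k,) or (n, k); ``u`` is (n,)."""
    if cdf.ndim == 1:
        idx = np.searchsorted(cdf, u, side="right")
    else:
        idx = (u[:, None] >= cdf).sum(axis=1)
    return np.minimum(idx, cdf.shape[-1] - 1)


def simulate_codes(
    profile: PhaseProfile, ppd: int, n_sessions: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate ``n_sessions`` independent 25-slot sessions as code indices.

    Returns an int array of shape ``(n_sessions, 25)`` indexing into
    :data:`~maternet.ethogram.CODES`.  Slot 0 is drawn from the initial
    distribution; each later slot switches with probability ``f_d`` and, given
    a switch, draws its destination from the kernel row of the current state.
    """
    f = profile.effective_fragmentation(ppd)
    init_cdf = np.cumsum(profile.initial_dist)
    kernel_cdf = np.cumsum(profile.switch_kernel, axis=1)
    out = np.empty((n_sessions, SLOTS_PER_PERIOD), dtype=np.int64)
    out[:, 0] = _draw_categorical(init_cdf, rng.random(n_sessions))
    for t in range(1, SLOTS_PER_PERIOD):
        cur = out[:, t - 1]
        switch = rng.random(n_sessions) < f
        dest = _draw_categorical(kernel_cdf[cur], rng.random(n_sessions))
        out[:, t] = np.where(switch, dest, cur)
    return out


def simulate_session(
    profile: PhaseProfile, ppd: int, rng: np.random.Generator
) -> tuple[str, ...]:
    """Simulate a single session and return its 25 behavior codes."""
    idx = simulate_codes(profile, ppd, 1, rng)[0]
    return tuple(CODES[i] for i in idx)


def _dam_rng(seed: int, group_index: int, dam_index: int) -> np.random.Generator:
    # Stable per-dam stream: spawn key identifies the dam, so adding dams
    # never perturbs the draws of existing ones.
    ss = np.random.SeedSequence(seed, spawn_key=(group_index, dam_index))
    return np.random.default_rng(ss)


def simulate_dataset(config: SimConfig) -> Dataset:
    """Simulate a full experiment: every dam x PPD x period session.

    Deterministic given ``config.seed``.  AM and PM periods draw from the
    group's LIGHT profile, DARK from its dark profile; within one dam the
    sessions are generated in (ppd, AM, PM, DARK) order from that dam's
    private stream.
    """
    sessions: list[ObservationSession] = []
    prefix = {"CTRL": "C", "LBN": "L"}
    for gi, group in enumerate(GROUPS):
        for di in range(config.n_dams_per_group):
            dam_id = f"{prefix[group]}{di + 1:02d}"
            rng = _dam_rng(config.seed, gi, di)
            for ppd in config.ppds:
                for period in PERIODS:
                    profile = config.profiles[(group, PERIOD_PHASE[period])]
                    sessions.append(
                        ObservationSession(
                            dam_id=dam_id,
                            group=group,
                            ppd=ppd,
                            period=period,
                            codes=simulate_session(profile, ppd, rng),
                        )
                    )
    metadata = {
        "generator": "maternet.simulate",
        "seed": config.seed,
        "n_dams_per_group": config.n_dams_per_group,
        "ppd_range": list(config.ppd_range),
    }
    return Dataset(sessions=sessions, metadata=metadata)
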