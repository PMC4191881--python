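"""Synthetic titration data for parameter-recovery experiments.

Emulates equilibrium in vitro titrations: a fixed core RNAP concentration,
one sigma species (or an equimolar mix) titrated over a concentration grid,
and a readout proportional to signal — hence multiplicative Gaussian
measurement noise, y -> y * (1 + eps) with eps ~ N(0, noise_sd^2) truncated
at +/- 3 sd (which keeps the noise unbiased and the readout within
[0, 1 + 3*noise_sd]).  Every generator takes an explicit seed; there is no
hidden global random state.

What these curves do not emulate: pipetting/series correlations, baseline
offsets, gel-band saturation, or any systematic deviation from the binding
model itself — recovery tests therefore probe the estimator, not the assay.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DomainError, UsageError, check_nonnegative
from .fitting import (TitrationDataset, binding_curve, mix_fractions,
                      transcription_curve)

#: Default assay design: core concentration of the mixed-reconstitution assay.
DEFAULT_CORE_TOTAL = 400e-9


def _apply_noise(y: np.ndarray, noise_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0.0:
        return y.copy()
    eps = np.clip(rng.normal(0.0, noise_sd, size=y.shape),
                  -3.0 * noise_sd, 3.0 * noise_sd)
    return np.clip(y * (1.0 + eps), 0.0, None)


def simulate_binding_titration(kd: float, core_total: float,
                               x: Sequence[float], noise_sd: float = 0.0,
                               seed: int | None = None) -> TitrationDataset:
    """Noisy holoenzyme-fraction curve from the exact single-species model."""
    check_nonnegative(noise_sd=noise_sd)
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    y = _apply_noise(binding_curve(x, core_total, kd), noise_sd, rng)
    return TitrationDataset(x=x, y=y, y_kind="holo_fraction",
                            core_total=core_total, noise_sd=noise_sd, seed=seed)


def simulate_transcription_titration(kd: float, km: float, core_total: float,
                                     x: Sequence[float], noise_sd: float = 0.0,
                                     seed: int | None = None) -> TitrationDataset:
    """Noisy normalized transcription-rate curve (binding + Michaelis-Menten)."""
    check_nonnegative(noise_sd=noise_sd)
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    y = _apply_noise(transcription_curve(x, core_total, kd, km), noise_sd, rng)
    return TitrationDataset(x=x, y=y, y_kind="normalized_rate",
                            core_total=core_total, noise_sd=noise_sd, seed=seed)


def simulate_mix_titration(rel_kds: dict[str, float], core_total: float,
                           x: Sequence[float], noise_sd: float = 0.0,
                           seed: int | None = None) -> list[TitrationDataset]:
    """Equimolar competition mix: per-species bound-fraction curves.

    The forward model is the strong-binding partition (kd ratios only),
    matching the regime of nM-scale binding at hundreds-of-nM concentrations.
    """
    check_nonnegative(noise_sd=noise_sd)
    if len(rel_kds) < 2:
        raise UsageError("a mix needs at least 2 species")
    x = np.asarray(x, dtype=float)
    names = list(rel_kds)
    r = [rel_kds[n] for n in names]
    rng = np.random.default_rng(seed)
    clean = np.stack([mix_fractions(xi, r, core_total) for xi in x], axis=1)
    out = []
    for i, name in enumerate(names):
        y = _apply_noise(clean[i], noise_sd, rng)
        out.append(TitrationDataset(x=x, y=y, y_kind="bound_fraction",
                                    core_total=core_total, species=name,
                                    noise_sd=noise_sd, seed=seed))
    return out


def simulate_titration(kind: str, *, x: Sequence[float],
                       core_total: float = DEFAULT_CORE_TOTAL,
                       noise_sd: float = 0.0, seed: int | None = None,
                       **truth) -> TitrationDataset | list[TitrationDataset]:
    """Dispatch on assay kind: 'binding', 'transcription' or 'mix'.

    ``truth`` carries the generating parameters: ``kd`` (binding),
    ``kd, km`` (transcription) or ``rel_kds`` (mix).
    """
    if kind == "binding":
        return simulate_binding_titration(truth["kd"], core_total, x,
                                          noise_sd, seed)
    if kind == "transcription":
        return simulate_transcription_titration(truth["kd"], truth["km"],
                                                core_total, x, noise_sd, seed)
    if kind == "mix":
        return simulate_mix_titration(truth["rel_kds"], core_total, x,
                                      noise_sd, seed)
    raise UsageError(f"unknown titration kind {kind!r}")
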