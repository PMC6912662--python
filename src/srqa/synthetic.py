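"""Surrogate RR interval generators for sinus rhythm and atrial fibrillation.

The sinus surrogate is a quasi-periodic series: a fixed mean interval with a
sinusoidal modulation (coarsely mimicking respiratory sinus arrhythmia) plus
small Gaussian beat-to-beat noise.  The AF surrogate reflects the standard
characterisation of fibrillation as a near-random interval sequence with
markedly increased variability: i.i.d. uniform intervals by default, with an
optional first-order serial correlation realised through a Gaussian copula
so the uniform marginal is preserved.

All generators take an explicit integer seed and use numpy's PCG64
generator, so records are bit-reproducible across platforms; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .features import RRRecord

__all__ = ["GeneratorConfig", "gen_ns_record", "gen_af_record", "gen_mixed_record"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the two surrogate rhythms (all times in milliseconds).

    Sinus: ``RR_t = ns_mean_ms + ns_mod_amp_ms * sin(2 pi t /
    ns_mod_period_beats) + N(0, ns_noise_sd_ms)``.  The 4-beat modulation
    period guarantees both monotone and non-monotone ordinal patterns occur,
    so every symbol-rate covariate is exercised.

    AF: intervals uniform on [af_min_ms, af_max_ms]; ``af_corr`` (0 to 0.3)
    adds lag-1 serial correlation via a Gaussian copula.
    """

    ns_mean_ms: float = 800.0
    ns_mod_amp_ms: float = 40.0
    ns_mod_period_beats: float = 4.0
    ns_noise_sd_ms: float = 10.0
    af_min_ms: float = 400.0
    af_max_ms: float = 1100.0
    af_corr: float = 0.0

    def __post_init__(self) -> None:
        if min(
            self.ns_mean_ms,
            self.ns_mod_amp_ms,
            self.ns_mod_period_beats,
            self.ns_noise_sd_ms,
        ) < 0:
            raise ValueError("sinus generator parameters must be non-negative")
        if self.ns_mean_ms <= 0:
            raise ValueError("ns_mean_ms must be positive")
        if not 0 < self.af_min_ms < self.af_max_ms:
            raise ValueError("need 0 < af_min_ms < af_max_ms")
        if not 0 <= self.af_corr <= 0.3:
            raise ValueError("af_corr must lie in [0, 0.3]")


def gen_ns_record(
    cfg: GeneratorConfig, n_beats: int, seed: int, record_id: str = "ns"
) -> RRRecord:
    """Quasi-periodic sinus-rhythm surrogate; all beats labelled N."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_beats + 1, dtype=float)
    rr = (
        cfg.ns_mean_ms
        + cfg.ns_mod_amp_ms * np.sin(2.0 * np.pi * t / cfg.ns_mod_period_beats)
        + rng.normal(0.0, cfg.ns_noise_sd_ms, n_beats)
    )
    rr = np.maximum(rr, 1.0)  # physiological floor; unreachable at defaults
    return RRRecord(record_id=record_id, rr_ms=rr, beat_rhythm=np.full(n_beats, "N", dtype=object))


def gen_af_record(
    cfg: GeneratorConfig, n_beats: int, seed: int, record_id: str = "af"
) -> RRRecord:
    """High-variability AF surrogate; all beats labelled AF.

    With ``af_corr = 0`` the intervals are i.i.d. uniform on
    [af_min_ms, af_max_ms], so all 6 ordinal patterns are equally likely.
    With ``af_corr > 0`` a stationary AR(1) Gaussian latent series is pushed
    through its CDF, giving lag-1 dependence with the same uniform marginal.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)
    if cfg.af_corr == 0.0:
        u = rng.uniform(0.0, 1.0, n_beats)
    else:
        rho = cfg.af_corr
        z = np.empty(n_beats)
        z[0] = rng.normal()
        innov = rng.normal(0.0, np.sqrt(1.0 - rho**2), n_beats - 1)
        for i in range(1, n_beats):
            z[i] = rho * z[i - 1] + innov[i - 1]
        u = norm.cdf(z)
    rr = cfg.af_min_ms + (cfg.af_max_ms - cfg.af_min_ms) * u
    return RRRecord(
        record_id=record_id, rr_ms=rr, beat_rhythm=np.full(n_beats, "AF", dtype=object)
    )


def gen_mixed_record(
    cfg: GeneratorConfig,
    segments: Sequence[tuple[str, int]],
    seed: int,
    record_id: str = "mixed",
) -> RRRecord:
    """Concatenate sinus and AF segments — a paroxysmal-AF surrogate.

    ``segments`` is a list of ``(rhythm, n_beats)`` with rhythm "N" or "AF";
    per-beat labels follow the generating segment, so windows spanning a
    transition exercise the majority labelling rule.
    """
    if not segments:
        raise ValueError("need at least one segment")
    rng = np.random.default_rng(seed)
    parts = []
    for rhythm, n_beats in segments:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if rhythm == "N":
            parts.append(gen_ns_record(cfg, n_beats, sub_seed))
        elif rhythm == "AF":
            parts.append(gen_af_record(cfg, n_beats, sub_seed))
        else:
            raise ValueError(f"unknown segment rhythm {rhythm!r}")
    return RRRecord(
        record_id=record_id,
        rr_ms=np.concatenate([p.rr_ms for p in parts]),
        beat_rhythm=np.concatenate([p.beat_rhythm for p in parts]),
    )
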