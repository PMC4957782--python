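"""Statistical laws of renal arterial geometry.

Four sampling laws drive the tree generator:

* daughter diameter vs parent diameter -- Gaussian, cubic mean / linear SD;
* vessel length vs vessel diameter -- Gaussian, linear mean / linear SD;
* spacing between neighboring afferent-arteriole origins -- exponential;
* afferent-arteriole diameter -- Gaussian.

The micro-CT and optical-clearing literature this is modeled on reports the
fits only graphically, so the packaged default coefficients are approximate
digitizations, calibrated so that generated whole-kidney trees reproduce
realistic afferent-arteriole counts (see docs/methods.md). Every operation
takes the distribution set explicitly, so the defaults are replaceable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MorphometryError",
    "ExtrapolationWarning",
    "MorphometricDistributions",
    "ExponentialFit",
    "load_profile",
    "sample_daughter_diameter",
    "sample_vessel_length",
    "sample_aa_spacing",
    "sample_aa_diameter",
    "fit_exponential_spacing",
]

#: Measured optically cleared tissue is shrunken by ~20% per axis; distances
#: measured on cleared tissue are multiplied by this factor to recover
#: in-vivo scale when the correction flag is set.
SHRINKAGE_CORRECTION = 1.0 / 0.8

_TRUNC_RETRIES = 100


class MorphometryError(ValueError):
    """Invalid input to a morphometric sampler or fitter."""


class ExtrapolationWarning(UserWarning):
    """A fit was evaluated outside the diameter range it was fitted on."""


@dataclass(frozen=True)
class MorphometricDistributions:
    """Parameter set for the four geometric sampling laws.

    Polynomial coefficients are in ascending order (c0, c1, ...), diameters
    and lengths in micrometers, ``aa_spacing_rate`` in 1/um.
    """

    ddp_mean_coeffs: tuple  # cubic: mean daughter diameter vs parent diameter
    ddp_sd_coeffs: tuple    # linear: SD of daughter diameter vs parent diameter
    vlvd_mean_coeffs: tuple  # linear: mean length vs diameter
    vlvd_sd_coeffs: tuple    # linear: SD of length vs diameter
    aa_spacing_rate: float   # exponential rate for inter-arteriole spacing
    aa_diam_mean: float
    aa_diam_sd: float
    valid_diameter_range: tuple = (20.0, 530.0)
    name: str = "unnamed"

    def __post_init__(self):
        if self.aa_spacing_rate <= 0:
            raise MorphometryError("aa_spacing_rate must be > 0")
        if self.aa_diam_mean <= 0:
            raise MorphometryError("aa_diam_mean must be > 0")
        if self.aa_diam_sd < 0 or self._ddp_sd(self.valid_diameter_range[0]) < 0 \
                or self._ddp_sd(self.valid_diameter_range[1]) < 0:
            raise MorphometryError("standard deviations must be non-negative")

    # -- fit evaluation ----------------------------------------------------

    def _check_range(self, diam):
        lo, hi = self.valid_diameter_range
        if diam < lo or diam > hi:
            warnings.warn(
                f"diameter {diam:.3g} um outside fitted range [{lo:g}, {hi:g}] um; "
                "extrapolating", ExtrapolationWarning, stacklevel=3)

    def ddp_mean(self, parent_diam):
        return float(np.polynomial.polynomial.polyval(parent_diam, self.ddp_mean_coeffs))

    def _ddp_sd(self, parent_diam):
        return float(np.polynomial.polynomial.polyval(parent_diam, self.ddp_sd_coeffs))

    def ddp_sd(self, parent_diam):
        return max(self._ddp_sd(parent_diam), 0.0)

    def vlvd_mean(self, diam):
        return float(np.polynomial.polynomial.polyval(diam, self.vlvd_mean_coeffs))

    def vlvd_sd(self, diam):
        return max(float(np.polynomial.polynomial.polyval(diam, self.vlvd_sd_coeffs)), 0.0)


@dataclass
class ExponentialFit:
    """Maximum-likelihood exponential rate with a bootstrap percentile CI."""

    rate: float            # 1/um
    ci_low: float
    ci_high: float
    n: int
    shrinkage_corrected: bool = False


# ---------------------------------------------------------------------------
# profiles

def _profile_path(name: str) -> Path:
    p = Path(name)
    if p.suffix in (".yaml", ".yml") and p.exists():
        return p
    return Path(str(resources.files("renalnet").joinpath(f"profiles/{name}.yaml")))


def load_profile(name: str = "default") -> MorphometricDistributions:
    """Load a packaged morphometric profile (``default``, ``degenerate``) or
    a YAML file path with the same schema."""
    path = _profile_path(name)
    if not path.exists():
        raise MorphometryError(f"no morphometric profile {name!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return MorphometricDistributions(
        ddp_mean_coeffs=tuple(raw["ddp_mean_coeffs"]),
        ddp_sd_coeffs=tuple(raw["ddp_sd_coeffs"]),
        vlvd_mean_coeffs=tuple(raw["vlvd_mean_coeffs"]),
        vlvd_sd_coeffs=tuple(raw["vlvd_sd_coeffs"]),
        aa_spacing_rate=float(raw["aa_spacing_rate"]),
        aa_diam_mean=float(raw["aa_diam_mean"]),
        aa_diam_sd=float(raw["aa_diam_sd"]),
        valid_diameter_range=tuple(raw.get("valid_diameter_range", (20.0, 530.0))),
        name=raw.get("name", path.stem),
    )


# ---------------------------------------------------------------------------
# sampling

def _truncated_normal(mean, sd, lo, hi, rng):
    """Gaussian draw restricted to the open interval (lo, hi).

    Rejection sampling with a bounded retry count; on exhaustion the draw is
    clamped just inside the nearer boundary, so pathological configurations
    degrade gracefully instead of looping.
    """
    if sd == 0.0:
        x = mean
    else:
        for _ in range(_TRUNC_RETRIES):
            x = mean + sd * rng.standard_normal()
            if lo < x < hi:
                return x
        x = mean
    if x <= lo or x >= hi:
        span = hi - lo if np.isfinite(hi) else max(abs(lo), 1.0)
        eps = 1e-9 * max(span, 1.0)
        x = min(max(x, lo + eps), (hi - eps) if np.isfinite(hi) else x)
        x = max(x, lo + eps)
    return x


def sample_daughter_diameter(parent_diam: float,
                             dists: MorphometricDistributions,
                             rng: np.random.Generator) -> float:
    """Draw the first daughter diameter (um) at a bifurcation.

    Gaussian with cubic mean / linear SD in the parent diameter, truncated to
    (0, parent_diam) so the Murray complement of the pair stays real.
    """
    if parent_diam <= 0:
        raise MorphometryError("parent diameter must be > 0")
    dists._check_range(parent_diam)
    return _truncated_normal(dists.ddp_mean(parent_diam), dists.ddp_sd(parent_diam),
                             0.0, parent_diam, rng)


def sample_vessel_length(diam: float,
                         dists: MorphometricDistributions,
                         rng: np.random.Generator) -> float:
    """Draw a vessel length (um) given its diameter; truncated positive."""
    if diam <= 0:
        raise MorphometryError("vessel diameter must be > 0")
    dists._check_range(diam)
    return _truncated_normal(dists.vlvd_mean(diam), dists.vlvd_sd(diam),
                             0.0, np.inf, rng)


def sample_aa_spacing(dists: MorphometricDistributions,
                      rng: np.random.Generator) -> float:
    """Exponential spacing (um) between neighboring arteriole origins.

    Support includes zero: arterioles frequently originate in doublets or
    triplets, i.e. at (near-)zero separation.
    """
    return rng.exponential(1.0 / dists.aa_spacing_rate)


def sample_aa_diameter(dists: MorphometricDistributions,
                       rng: np.random.Generator,
                       feeding_diam: float | None = None) -> float:
    """Afferent-arteriole diameter (um): truncated Gaussian, capped below the
    feeding-vessel diameter when one is supplied."""
    hi = feeding_diam if feeding_diam is not None else np.inf
    if hi <= 0:
        raise MorphometryError("feeding diameter must be > 0")
    return _truncated_normal(dists.aa_diam_mean, dists.aa_diam_sd, 0.0, hi, rng)


# ---------------------------------------------------------------------------
# fitting

def fit_exponential_spacing(distances,
                            n_boot: int = 1000,
                            ci: float = 0.95,
                            shrinkage_correction: bool = False,
                            rng: np.random.Generator | None = None) -> ExponentialFit:
    """ML fit of the exponential rate for inter-arteriole distances.

    lambda_hat = 1/mean(distances); the CI is a bootstrap percentile interval.
    With ``shrinkage_correction`` the input distances (assumed measured on
    cleared, shrunken tissue) are rescaled by 1/0.8 per axis first.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise MorphometryError("need at least two distances")
    if np.any(d < 0):
        raise MorphometryError("distances must be non-negative")
    if np.all(d == 0):
        raise MorphometryError("all distances are zero; rate is undefined")
    if shrinkage_correction:
        d = d * SHRINKAGE_CORRECTION
    rate = 1.0 / d.mean()
    rng = np.random.default_rng(0) if rng is None else rng
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot_means = d[idx].mean(axis=1)
    boot_rates = 1.0 / boot_means[boot_means > 0]
    lo, hi = np.quantile(boot_rates, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return ExponentialFit(rate=float(rate), ci_low=float(lo), ci_high=float(hi),
                          n=int(d.size), shrinkage_corrected=shrinkage_correction)
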