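"""Locating the transient complex on the sigma_chi vs N_c transition.

Within the native well the spin angle chi of clash-free configurations is
tightly restricted; as contacts are lost the allowed rotation range opens
up sharply.  Binning clash-free configurations by their integer contact
count N_c and measuring the spread of chi in each bin produces a sigmoidal
profile, which is fit with the two-state form used for protein denaturation
data:

    sigma_chi(N_c) = sigma_n + (sigma_u - sigma_n) / (1 + exp((N_c - N_c*) / w))

with folded/bound baseline sigma_n (high N_c), unbound baseline sigma_u
(low N_c) and width w > 0.  The midpoint N_c*, rounded to the nearest
integer (ties toward the unbound side), defines the transient-complex
ensemble: all sampled clash-free configurations with N_c exactly equal to
the rounded N_c*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, ComputationError
from .sampling import EnsembleStore


def _round_half_down(x: float) -> int:
    """Nearest integer; exact .5 ties round down (toward the unbound side)."""
    return int(math.ceil(x - 0.5))


def two_state_sigma(nc, sigma_n, sigma_u, nc_star, width):
    """The constant-baseline two-state transition curve."""
    return sigma_n + (sigma_u - sigma_n) / (1.0 + np.exp((nc - nc_star) / width))


def two_state_sigma_sloped(nc, sigma_n, slope_n, sigma_u, slope_u, nc_star, width):
    """Variant with linear baselines on both sides."""
    f = 1.0 / (1.0 + np.exp((nc - nc_star) / width))
    return (sigma_n + slope_n * nc) * (1 - f) + (sigma_u + slope_u * nc) * f


@dataclass
class TransitionProfile:
    """sigma_chi per integer N_c bin plus (optionally) the two-state fit."""

    nc: np.ndarray                      # integer bin values, 0..max observed
    counts: np.ndarray                  # clash-free configurations per bin
    sigma_chi: np.ndarray               # NaN where the bin is empty
    min_count: int = 50
    sigma_mode: str = "rms"             # rms about native chi=0, or "std"

    sigma_n: float | None = None
    sigma_u: float | None = None
    nc_star: float | None = None
    width: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def usable(self) -> np.ndarray:
        return (self.counts >= self.min_count) & np.isfinite(self.sigma_chi)

    @property
    def fitted(self) -> bool:
        return self.nc_star is not None

    @property
    def nc_star_rounded(self) -> int:
        if not self.fitted:
            raise FitError("profile has not been fitted")
        return _round_half_down(self.nc_star)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "n_c": self.nc, "count": self.counts, "sigma_chi": self.sigma_chi,
            "used_in_fit": self.usable,
        })
        if self.fitted:
            df["fit"] = two_state_sigma(self.nc, self.sigma_n, self.sigma_u,
                                        self.nc_star, self.width)
        return df

    def fit_summary(self) -> dict:
        if not self.fitted:
            raise FitError("profile has not been fitted")
        return {
            "sigma_n": self.sigma_n,
            "sigma_u": self.sigma_u,
            "nc_star": self.nc_star,
            "nc_star_rounded": self.nc_star_rounded,
            "width": self.width,
            **self.diagnostics,
        }

    def save(self, table_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(self.fit_summary(), fh, indent=2, sort_keys=True)

    def plot(self, ax=None):
        """Mirror of the sigma_chi vs N_c transition figure (optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.usable
        ax.plot(self.nc[ok], self.sigma_chi[ok], "o", label="clash-free sample")
        if self.fitted:
            xs = np.linspace(self.nc.min(), self.nc.max(), 200)
            ax.plot(xs, two_state_sigma(xs, self.sigma_n, self.sigma_u,
                                        self.nc_star, self.width),
                    "-", label=f"two-state fit, $N_c^*$={self.nc_star:.2f}")
            ax.axvline(self.nc_star, ls="--", color="gray")
        ax.set_xlabel("$N_c$")
        ax.set_ylabel(r"$\sigma_\chi$ (deg)")
        ax.legend()
        return ax


def build_profile(
    store: EnsembleStore,
    min_count: int = 50,
    sigma_mode: str = "rms",
) -> TransitionProfile:
    """Bin chi spread per integer N_c over the clash-free sample.

    ``sigma_mode='rms'`` measures the spread about the native value chi = 0
    (sqrt of the mean squared chi), which is the natural width of a well
    centered on the native placement; ``'std'`` uses the ordinary standard
    deviation about the bin mean for comparison.
    """
    if sigma_mode not in ("rms", "std"):
        raise ComputationError(f"unknown sigma_mode {sigma_mode!r}")
    if len(store) == 0:
        raise InsufficientDataError("ensemble store is empty")
    if (store.n_c < 0).any():
        raise ComputationError("store has configurations without N_c")
    nc_max = int(store.n_c.max())
    nc = np.arange(nc_max + 1)
    counts = np.bincount(store.n_c, minlength=nc_max + 1)
    sigma = np.full(nc_max + 1, np.nan)
    for k in range(nc_max + 1):
        chis = store.chi[store.n_c == k]
        if len(chis) == 0:
            continue
        if sigma_mode == "rms":
            sigma[k] = float(np.sqrt(np.mean(chis ** 2)))
        else:
            sigma[k] = float(np.std(chis))
    profile = TransitionProfile(nc=nc, counts=counts, sigma_chi=sigma,
                                min_count=min_count, sigma_mode=sigma_mode)
    if int(profile.usable.sum()) < 4:
        raise InsufficientDataError(
            f"only {int(profile.usable.sum())} N_c bins hold >= {min_count} "
            "configurations; need at least 4 to characterize the transition"
        )
    return profile


def fit_two_state(
    profile: TransitionProfile,
    sloped_baselines: bool = False,
) -> TransitionProfile:
    """Least-squares fit of the two-state transition; fills the fit fields.

    Raises :class:`FitError` on non-convergence, a midpoint outside the
    observed N_c range, or inverted baselines (sigma_u <= sigma_n would mean
    rotational freedom shrinking as contacts are lost).
    """
    ok = profile.usable
    x = profile.nc[ok].astype(float)
    y = profile.sigma_chi[ok]
    if len(x) < 4:
        raise InsufficientDataError("fewer than 4 usable bins")
    s_lo, s_hi = float(y.min()), float(y.max())
    mid_guess = float(x[np.argmin(np.abs(y - 0.5 * (s_lo + s_hi)))])

    try:
        if sloped_baselines:
            p0 = [s_lo, 0.0, s_hi, 0.0, mid_guess, 1.0]
            bounds = ([0, -np.inf, 0, -np.inf, x.min() - 5, 1e-6],
                      [np.inf, np.inf, np.inf, np.inf, x.max() + 5, np.inf])
            popt, pcov = curve_fit(two_state_sigma_sloped, x, y, p0=p0,
                                   bounds=bounds, maxfev=20000)
            sigma_n, _, sigma_u, _, nc_star, width = popt
        else:
            p0 = [s_lo, s_hi, mid_guess, 1.0]
            bounds = ([0, 0, x.min() - 5, 1e-6],
                      [np.inf, np.inf, x.max() + 5, np.inf])
            popt, pcov = curve_fit(two_state_sigma, x, y, p0=p0,
                                   bounds=bounds, maxfev=20000)
            sigma_n, sigma_u, nc_star, width = popt
    except RuntimeError as exc:
        raise FitError(f"two-state fit did not converge: {exc}") from exc

    if not (x.min() - 1e-9 <= nc_star <= x.max() + 1e-9):
        raise FitError(
            f"fitted midpoint N_c* = {nc_star:.2f} lies outside the observed "
            f"N_c range [{x.min():.0f}, {x.max():.0f}]"
        )
    if sigma_u <= sigma_n:
        raise FitError(
            f"fit implies rotational freedom does not open up "
            f"(sigma_u = {sigma_u:.1f} <= sigma_n = {sigma_n:.1f})"
        )

    resid = y - (two_state_sigma_sloped(x, *popt) if sloped_baselines
                 else two_state_sigma(x, *popt))
    perr = np.sqrt(np.diag(pcov))
    profile.sigma_n = float(sigma_n)
    profile.sigma_u = float(sigma_u)
    profile.nc_star = float(nc_star)
    profile.width = float(width)
    profile.diagnostics = {
        "residual_norm": float(np.linalg.norm(resid)),
        "n_bins_fit": int(len(x)),
        "param_stderr": [float(v) for v in perr],
        "sloped_baselines": bool(sloped_baselines),
    }
    return profile


@dataclass
class TransientEnsemble:
    """All sampled clash-free configurations with N_c equal to N_c*."""

    nc_star: int
    members: EnsembleStore

    @property
    def member_count(self) -> int:
        return len(self.members)


def extract_ensemble(store: EnsembleStore, nc_star: int) -> TransientEnsemble:
    """Exact filter N_c == N_c* over the sample."""
    mask = store.n_c == int(nc_star)
    if not mask.any():
        raise ComputationError(
            f"no sampled configurations have N_c = {nc_star}; "
            "fit and sample are inconsistent"
        )
    return TransientEnsemble(nc_star=int(nc_star), members=store.select(mask))
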