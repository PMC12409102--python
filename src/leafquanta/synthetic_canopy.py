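"""Seeded generator of a synthetic canopy fluorescence campaign.

Emulates a tropical-forest PAM sampling design: three height strata
(0–20 m, 20–40 m, > 40 m), several trees per stratum, three branches per tree
at bottom/middle/top crown positions, and at least three leaves per branch,
measured in a wet and a dry season with distinct species pools.

The physical chain is mechanistic rather than curve-fitted:

1. Light attenuates through the canopy by Beer–Lambert extinction of
   top-of-canopy PAR through the cumulative leaf area above the measurement
   height, with multiplicative lognormal "sunfleck" noise; VPD (and air
   temperature) increase linearly with height plus Gaussian noise.
2. The PSII regulatory state responds to the microenvironment:
   NPQt follows a saturating Hill curve in PAR scaled up by VPD and a
   lognormal species effect; qL declines from 1 toward a floor with PAR.
3. Raw fluorescence signals (Fs, Fm', Fo') are produced by the exact inverse
   fluorescence model and perturbed with multiplicative measurement noise;
   a small seeded fraction of rows is corrupted (Fs pushed above Fm') to
   exercise the QC filter.

Because ΦNO = 1/(1 + 4.88·qL + NPQt) and ΦPSII = 4.88·qL·ΦNO, the composed
noise-free response curves have closed form; :func:`noise_free_curves` exposes
them and :func:`analytic_breakpoints` locates the exact PAR values where
d(4.88·qL + NPQt)/dPAR changes sign — the generator's ground-truth quenching
phase boundaries that downstream breakpoint detection is tested against.
With the default dry-season physiology NPQt saturates while qL keeps falling
at extreme PAR, so ΦNO rises again and the ΦNO–ΦPSII curve is triphasic; the
default wet season (lower light ceiling, weaker and slower-saturating NPQ)
yields a single phase shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .fluor_core import K_DARK, PhotoState, forward_fluorescence, derive_vpd

__all__ = [
    "SeasonPhysiology",
    "SyntheticConfig",
    "simulate_microenvironment",
    "simulate_photostate",
    "simulate_campaign",
    "noise_free_curves",
    "analytic_breakpoints",
]


@dataclass(frozen=True)
class SeasonPhysiology:
    """Season-specific physiology and atmosphere parameters.

    NPQt light response: ``npq_max · PAR^n/(par50^n + PAR^n) · (1 + beta_vpd·VPD)``
    (Hill exponent ``hill_n``, half-saturation ``par50`` in µmol m⁻² s⁻¹).
    qL light response: ``ql_floor + (1 − ql_floor)/(1 + PAR/ql_par50)^ql_m``.
    """

    par_top: float          # top-of-canopy PAR, µmol m⁻² s⁻¹
    vpd_floor: float        # kPa at ground level
    vpd_top: float          # kPa at canopy top
    temp_floor: float       # °C at ground level
    temp_top: float         # °C at canopy top
    npq_max: float
    par50: float
    hill_n: float
    beta_vpd: float         # per kPa multiplier on NPQt
    ql_par50: float
    ql_m: float
    ql_floor: float
    n_species: int
    species_sd: float       # sd of lognormal species effect on NPQt


# Defaults emulate a tall evergreen tropical forest. The dry season has a
# higher light ceiling, a weaker NPQ ceiling that saturates sharply, and a
# heavy-tailed qL decline (photoinhibition-primed leaves keep closing centers
# at extreme PAR), so ΦNO bottoms out and rises again — the high-stress phase.
# The wet season has a lower ceiling with gentler, later-saturating NPQ and a
# thin-tailed qL response, so its ΦNO(PAR) curve has a single maximum. The
# atmospheric height trends are shared between seasons; seasonal VPD contrast
# enters through beta_vpd and the light ceiling.
DRY_DEFAULT = SeasonPhysiology(
    par_top=2000.0, vpd_floor=0.8, vpd_top=2.8, temp_floor=26.0, temp_top=32.0,
    npq_max=3.5, par50=280.0, hill_n=3.5, beta_vpd=0.02,
    ql_par50=120.0, ql_m=0.60, ql_floor=0.03,
    n_species=18, species_sd=0.20,
)
WET_DEFAULT = SeasonPhysiology(
    par_top=1400.0, vpd_floor=0.8, vpd_top=2.8, temp_floor=26.0, temp_top=32.0,
    npq_max=4.5, par50=380.0, hill_n=1.8, beta_vpd=0.06,
    ql_par50=230.0, ql_m=1.5, ql_floor=0.06,
    n_species=14, species_sd=0.15,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; the seed fully determines the output."""

    seed: int = 0
    n_trees_per_stratum: int = 45
    branches_per_tree: int = 3
    leaves_per_branch: int = 4
    seasons: tuple[str, ...] = ("wet", "dry")
    # canopy optics: two-layer leaf-area density (LAI per layer), heights in m
    canopy_top: float = 52.0
    understory_lai: float = 3.4     # spread over 0–20 m
    crown_lai: float = 2.4          # spread over 25–45 m
    extinction_k: float = 0.62      # Beer–Lambert, per unit LAI
    sunfleck_sigma: float = 0.35    # lognormal sd of PAR noise (log scale)
    vpd_noise_sd: float = 0.15      # kPa
    temp_noise_sd: float = 0.6      # °C
    # physiology noise (leaf-to-leaf, lognormal on NPQt / logit-scale on qL)
    npqt_leaf_sd: float = 0.15
    ql_leaf_sd: float = 0.15
    # measurement noise on raw fluorescence signals (multiplicative, Gaussian)
    fluor_noise_sd: float = 0.004
    corrupt_frac: float = 0.05      # fraction of rows with Fs pushed above Fm'
    dry: SeasonPhysiology = field(default_factory=lambda: DRY_DEFAULT)
    wet: SeasonPhysiology = field(default_factory=lambda: WET_DEFAULT)

    def physiology(self, season: str) -> SeasonPhysiology:
        if season == "dry":
            return self.dry
        if season == "wet":
            return self.wet
        raise ValueError(f"unknown season {season!r}")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# canopy structure

def cumulative_lai_above(height, config: SyntheticConfig):
    """Leaf area index integrated from ``height`` to the canopy top.

    Two homogeneous layers: an understory (0–20 m) and an upper crown layer
    (25–45 m); the gap and the zone above 45 m hold no foliage.
    """
    h = np.asarray(height, dtype=float)
    under = config.understory_lai / 20.0 * np.clip(20.0 - h, 0.0, 20.0)
    crown = config.crown_lai / 20.0 * np.clip(45.0 - np.maximum(h, 25.0), 0.0, 20.0)
    out = under + crown
    return out if out.ndim else float(out)


def mean_par_at(height, season: str, config: SyntheticConfig):
    """Expected PAR at a height: Beer–Lambert extinction of top-of-canopy PAR."""
    phys = config.physiology(season)
    lai = cumulative_lai_above(height, config)
    return phys.par_top * np.exp(-config.extinction_k * np.asarray(lai))


def mean_vpd_at(height, season: str, config: SyntheticConfig):
    phys = config.physiology(season)
    frac = np.clip(np.asarray(height, dtype=float) / config.canopy_top, 0.0, 1.0)
    return phys.vpd_floor + (phys.vpd_top - phys.vpd_floor) * frac


def simulate_microenvironment(height, season: str, config: SyntheticConfig,
                              rng: np.random.Generator):
    """Draw (par, air_temp, rh, vpd) for leaves at the given heights.

    PAR gets multiplicative lognormal sunfleck noise (mean-one); VPD and air
    temperature get additive Gaussian noise around their linear height trends;
    RH is back-computed so that the Tetens derivation reproduces the VPD.
    """
    h = np.atleast_1d(np.asarray(height, dtype=float))
    if np.any(h < 0):
        raise ValueError("height must be >= 0")
    phys = config.physiology(season)
    sig = config.sunfleck_sigma
    par = mean_par_at(h, season, config) * rng.lognormal(
        -0.5 * sig ** 2, sig, size=h.shape)
    frac = np.clip(h / config.canopy_top, 0.0, 1.0)
    air_temp = (phys.temp_floor + (phys.temp_top - phys.temp_floor) * frac
                + rng.normal(0.0, config.temp_noise_sd, size=h.shape))
    vpd = np.maximum(
        mean_vpd_at(h, season, config)
        + rng.normal(0.0, config.vpd_noise_sd, size=h.shape), 0.02)
    es = 0.61078 * np.exp(17.27 * air_temp / (air_temp + 237.3))
    rh = np.clip(100.0 * (1.0 - vpd / es), 0.0, 100.0)
    # keep vpd exactly consistent with (T, RH) after clipping
    vpd = derive_vpd(air_temp, rh)
    return par, air_temp, rh, vpd


# ---------------------------------------------------------------------------
# physiology

def expected_photostate(par, vpd, season: str, config: SyntheticConfig,
                        species_effect=0.0):
    """Noise-free (qL, NPQt) response to PAR and VPD."""
    phys = config.physiology(season)
    par = np.asarray(par, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    hill = par ** phys.hill_n / (phys.par50 ** phys.hill_n + par ** phys.hill_n)
    npqt = (phys.npq_max * hill * (1.0 + phys.beta_vpd * vpd)
            * np.exp(np.asarray(species_effect, dtype=float)))
    ql = phys.ql_floor + (1.0 - phys.ql_floor) / (1.0 + par / phys.ql_par50) ** phys.ql_m
    return ql, npqt


def simulate_photostate(par, vpd, species_effect, season: str,
                        config: SyntheticConfig, rng: np.random.Generator) -> PhotoState:
    """Draw a PhotoState: expected response plus leaf-level noise.

    NPQt noise is mean-one lognormal; qL noise is Gaussian on the logit scale
    so draws stay strictly inside (0, 1].
    """
    ql_mu, npqt_mu = expected_photostate(par, vpd, season, config, species_effect)
    shape = np.broadcast(np.asarray(par), np.asarray(vpd)).shape or (1,)
    npqt = npqt_mu * rng.lognormal(-0.5 * config.npqt_leaf_sd ** 2,
                                   config.npqt_leaf_sd, size=shape)
    z = np.log(ql_mu / (1.0 - np.minimum(ql_mu, 1.0 - 1e-9)))
    ql = 1.0 / (1.0 + np.exp(-(z + rng.normal(0.0, config.ql_leaf_sd, size=shape))))
    return PhotoState(ql=np.clip(ql, 1e-6, 1.0), npqt=np.maximum(npqt, 0.0))


# ---------------------------------------------------------------------------
# campaign assembly

_STRATA_BANDS = {"S1": (2.0, 18.0), "S2": (22.0, 38.0), "S3": (41.0, 50.0)}
_BRANCH_OFFSETS = {"bottom": -3.0, "middle": 0.0, "top": 3.0}


def simulate_campaign(config: SyntheticConfig, with_truth: bool = False) -> pd.DataFrame:
    """Generate the full campaign table, one row per leaf measurement.

    Columns follow the reader's default schema (fs, fm_prime, fo_prime, par,
    air_temp, rh, vpd, height_m, species, season, tree_id, branch_position,
    leaf_id). With ``with_truth=True``, ground-truth columns (``true_ql``,
    ``true_npqt``, ``corrupted``) are appended for testing; readers ignore
    them. Identical configs (same seed) produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for season in config.seasons:
        phys = config.physiology(season)
        species_pool = [f"{season}_sp{i:02d}" for i in range(phys.n_species)]
        species_fx = rng.normal(0.0, phys.species_sd, size=phys.n_species)
        species_fx -= species_fx.mean()          # center: effects are contrasts
        for stratum, (lo, hi) in _STRATA_BANDS.items():
            for t in range(config.n_trees_per_stratum):
                tree_id = f"{season}_{stratum}_T{t:02d}"
                sp_idx = int(rng.integers(0, phys.n_species))
                crown_h = rng.uniform(lo + 3.0, hi)
                positions = list(_BRANCH_OFFSETS)[: config.branches_per_tree]
                for pos in positions:
                    bh = float(np.clip(crown_h + _BRANCH_OFFSETS[pos], 0.5,
                                       config.canopy_top))
                    for leaf in range(config.leaves_per_branch):
                        h = float(np.clip(bh + rng.normal(0.0, 0.4), 0.3,
                                          config.canopy_top))
                        par, tair, rh, vpd = simulate_microenvironment(
                            h, season, config, rng)
                        state = simulate_photostate(
                            par, vpd, species_fx[sp_idx], season, config, rng)
                        fs, fm, fo = forward_fluorescence(state)
                        noise = rng.normal(1.0, config.fluor_noise_sd, size=3)
                        rows.append(dict(
                            fs=float(fs[0] * noise[0]),
                            fm_prime=float(fm[0] * noise[1]),
                            fo_prime=float(fo[0] * noise[2]),
                            par=float(par[0]), air_temp=float(tair[0]),
                            rh=float(rh[0]), vpd=float(vpd[0]), height_m=h,
                            species=species_pool[sp_idx], season=season,
                            tree_id=tree_id, branch_position=pos,
                            leaf_id=f"{tree_id}_{pos}_L{leaf}",
                            true_ql=float(np.asarray(state.ql)[0]),
                            true_npqt=float(np.asarray(state.npqt)[0]),
                        ))
    df = pd.DataFrame(rows)
    # seeded corruption: push Fs above Fm' so ΦPSII (and ΦNPQ) go negative
    n_bad = int(round(config.corrupt_frac * len(df)))
    bad_idx = rng.choice(len(df), size=n_bad, replace=False) if n_bad else []
    corrupted = np.zeros(len(df), dtype=bool)
    corrupted[bad_idx] = True
    df.loc[corrupted, "fs"] = df.loc[corrupted, "fm_prime"] * rng.uniform(
        1.05, 1.3, size=n_bad)
    df["corrupted"] = corrupted
    if not with_truth:
        df = df.drop(columns=["true_ql", "true_npqt", "corrupted"])
    return df


# ---------------------------------------------------------------------------
# analytic ground truth

def noise_free_curves(season: str, config: SyntheticConfig,
                      par_grid: np.ndarray | None = None,
                      k: float = K_DARK) -> pd.DataFrame:
    """Closed-form ΦNO/ΦPSII/ΦNPQ along the mean canopy light gradient.

    PAR on the grid is mapped to the height of the mean light profile (clipped
    to the canopy) to pick the covarying mean VPD, then the expected (qL, NPQt)
    response gives ΦNO = 1/(1 + k·qL + NPQt) and ΦPSII = k·qL·ΦNO.
    """
    phys = config.physiology(season)
    if par_grid is None:
        par_floor = float(mean_par_at(0.0, season, config))
        par_grid = np.linspace(par_floor, phys.par_top, 2001)
    # invert the monotone mean PAR(height) profile numerically for VPD
    h_grid = np.linspace(0.0, config.canopy_top, 2001)
    par_h = mean_par_at(h_grid, season, config)
    heights = np.interp(par_grid, par_h, h_grid)   # par_h increasing in h
    vpd = mean_vpd_at(heights, season, config)
    ql, npqt = expected_photostate(par_grid, vpd, season, config)
    phi_no = 1.0 / (1.0 + k * ql + npqt)
    phi_psii = k * ql * phi_no
    return pd.DataFrame(dict(par=par_grid, height=heights, vpd=vpd, ql=ql,
                             npqt=npqt, phi_no=phi_no, phi_psii=phi_psii,
                             phi_npq=1.0 - phi_no - phi_psii))


def analytic_breakpoints(season: str, config: SyntheticConfig,
                         n_grid: int = 20001) -> pd.DataFrame:
    """Exact extrema of the noise-free ΦNO(PAR) curve.

    Breakpoints of the ΦNO–ΦPSII relationship are where dΦNO/dPAR changes
    sign, i.e. where d(4.88·qL + NPQt)/dPAR crosses zero. Located by a dense
    scan of the closed-form curve with sign-change bisection refinement.
    Returns one row per breakpoint: par, phi_psii, phi_no and the direction of
    the ΦNO slope change ('max' = phase shift, 'min' = stress onset).
    """
    curves = noise_free_curves(season, config,
                               par_grid=np.linspace(
                                   float(mean_par_at(0.0, season, config)),
                                   config.physiology(season).par_top, n_grid))
    par = curves["par"].to_numpy()
    phi_no = curves["phi_no"].to_numpy()
    d = np.diff(phi_no)
    sign = np.sign(d)
    flips = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    # numerical-derivative artifacts at the grid edges are not extrema
    margin = max(2, len(d) // 100)
    flips = flips[(flips > margin) & (flips < len(d) - margin)]
    rows = []
    for i in flips:
        # linear interpolation of the derivative zero crossing
        w = d[i - 1] / (d[i - 1] - d[i])
        p = par[i] + w * (par[i + 1] - par[i])
        interp = lambda col: float(np.interp(p, par, curves[col].to_numpy()))
        rows.append(dict(par=float(p), phi_psii=interp("phi_psii"),
                         phi_no=interp("phi_no"),
                         kind="max" if d[i - 1] > 0 else "min"))
    return pd.DataFrame(rows)
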