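"""Compression-curve metrics, Johnson-Cook failure strain, synthetic responses.

Engineering stress uses the cylindrical envelope cross-section pi (D/2)^2 —
the cellular-solids convention, so lattice stress sits alongside relative
density.  Energy absorption (EA) is the area under the engineering
stress-strain curve up to a fixed strain (0.5 by default); in MPa x strain
this is a volumetric energy density, MJ/m^3.

The synthetic generator stands in for explicit-dynamics FEA of Ti6Al4V
sheet lattices under quasi-static compression.  It composes

* an analytic sheet-lattice descriptor emulator: RD ~ c_type * t * mean(1/L)
  (a thin sheet of thickness t whose area per unit volume scales with 1/L),
  SA/VR ~ 2/t (two faces per sheet of thickness t), with mild cell-size
  modulation;
* a Gibson-Ashby power law for ultimate stress,
  U = k_type * sigma_0 * (RD/100)^n, with small documented rotation and
  aspect-ratio modifiers;
* an idealized bilinear (elastic then plateau) curve integrated to strain
  0.5 for EA;
* multiplicative lognormal noise of a given coefficient of variation,
  mean-corrected so the noise has unit expectation, seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_space import classify_size, designs_to_frame
from .geometry import LatticeDesign

#: Ti6Al4V constants carried from the source simulation setup (metadata
#: only; no solver is implemented here). Young's modulus MPa, Poisson ratio,
#: density kg/m^3 (as used by the mass-scaled explicit simulations).
TI6AL4V = {"youngs_modulus_mpa": 107_500.0, "poisson_ratio": 0.3,
           "density_kg_m3": 10_750.0}


@dataclass(frozen=True)
class JCDamageParams:
    """Johnson-Cook failure-strain constants.

    eps_f = (d1 + d2 exp(d3 eta)) (1 + d4 * rate_term) (1 + d5 * temp_term),
    eta = stress triaxiality.  Defaults are the compression-calibrated set
    for the Ti6Al4V sheet lattices (d4 = d5 = 0: no rate or thermal terms).
    """

    d1: float = 0.005
    d2: float = 0.55
    d3: float = -0.25
    d4: float = 0.0
    d5: float = 0.0


def jc_failure_strain(params: JCDamageParams, triaxiality: float,
                      rate_term: float = 0.0, temp_term: float = 0.0):
    """Johnson-Cook failure strain at the given stress triaxiality."""
    eta = np.asarray(triaxiality, dtype=float)
    out = ((params.d1 + params.d2 * np.exp(params.d3 * eta))
           * (1.0 + params.d4 * rate_term)
           * (1.0 + params.d5 * temp_term))
    return float(out) if out.ndim == 0 else out


@dataclass
class StressStrainCurve:
    """Engineering stress-strain samples (strain dimensionless, stress MPa)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.size < 2:
            raise ValueError("strain and stress must be equal-length, size >= 2")
        if (self.strain < 0).any() or (self.stress < 0).any():
            raise ValueError("strain and stress must be non-negative")
        d = np.diff(self.strain)
        if (d <= 0).any():
            idx = int(np.argmax(d <= 0))
            raise ValueError(f"strain must be strictly increasing "
                             f"(violated at sample {idx + 1})")


@dataclass
class MechanicalMetrics:
    ultimate_stress: float          # MPa
    energy_absorption: float        # MJ/m^3
    youngs_modulus: float           # MPa
    yield_strength: float           # MPa
    plateau_stress: float           # MPa
    ea_truncated: bool = False      # curve ended before the strain limit
    yield_flagged: bool = False     # no 0.2%-offset intersection found


def to_engineering_curve(force, displacement, diameter: float,
                         height: float) -> StressStrainCurve:
    """Convert force (N) vs displacement (mm) to engineering stress-strain.

    Stress normalizes by the envelope cross-section pi (D/2)^2; strain is
    displacement over the initial height.
    """
    force = np.asarray(force, dtype=float)
    disp = np.asarray(displacement, dtype=float)
    if force.shape != disp.shape:
        raise ValueError("force and displacement must have equal length")
    if diameter <= 0 or height <= 0:
        raise ValueError("diameter and height must be positive")
    d = np.diff(disp)
    if (d < 0).any():
        idx = int(np.argmax(d < 0))
        raise ValueError(f"displacement must be non-decreasing "
                         f"(violated at sample {idx + 1})")
    area = np.pi * (diameter / 2.0) ** 2
    strain = disp / height
    stress = force / area
    # drop duplicated strain stations (zero-displacement dwell)
    keep = np.concatenate([[True], np.diff(strain) > 0])
    return StressStrainCurve(strain[keep], stress[keep])


def ultimate_stress(curve: StressStrainCurve) -> float:
    """Maximum engineering stress reached during compression (MPa)."""
    return float(curve.stress.max())


def energy_absorption(curve: StressStrainCurve, strain_limit: float = 0.5,
                      return_flag: bool = False):
    """Area under the stress-strain curve up to ``strain_limit`` (MJ/m^3).

    Trapezoidal rule with linear interpolation of the segment crossing the
    limit.  If the curve ends early the integral runs to its end and the
    truncation flag is set (returned when ``return_flag``).
    """
    if strain_limit <= 0:
        raise ValueError("strain_limit must be > 0")
    eps, sig = curve.strain, curve.stress
    truncated = eps[-1] < strain_limit
    if not truncated:
        limit_stress = float(np.interp(strain_limit, eps, sig))
        mask = eps < strain_limit
        eps = np.append(eps[mask], strain_limit)
        sig = np.append(sig[mask], limit_stress)
    ea = float(np.trapezoid(sig, eps))
    return (ea, truncated) if return_flag else ea


def extended_metrics(curve: StressStrainCurve,
                     modulus_stress_window: tuple = (0.1, 0.4),
                     plateau_window: tuple = (0.2, 0.4),
                     offset: float = 0.002) -> MechanicalMetrics:
    """Modulus, yield, plateau and the primary U / EA metrics.

    The modulus is the least-squares slope through the samples whose stress
    lies in ``modulus_stress_window`` (fractions of the ultimate stress) on
    the rising branch — deterministic and robust to plateau onset.  Yield is
    the 0.2%-offset intersection; if the offset line never crosses the curve
    the first local maximum is reported with a flag.  Plateau stress is the
    mean over the ``plateau_window`` strain band.
    """
    u = ultimate_stress(curve)
    ea, truncated = energy_absorption(curve, return_flag=True)
    eps, sig = curve.strain, curve.stress

    i_peak = int(np.argmax(sig))
    rise_eps, rise_sig = eps[:i_peak + 1], sig[:i_peak + 1]
    lo, hi = (f * u for f in modulus_stress_window)
    sel = (rise_sig >= lo) & (rise_sig <= hi)
    if sel.sum() >= 2:
        x, y = rise_eps[sel], rise_sig[sel]
        modulus = float(np.polyfit(x, y, 1)[0])
    else:  # too few samples in the window: secant through it
        e_lo = float(np.interp(lo, rise_sig, rise_eps))
        e_hi = float(np.interp(hi, rise_sig, rise_eps))
        modulus = (hi - lo) / (e_hi - e_lo) if e_hi > e_lo else 0.0

    # 0.2 %-offset yield: first crossing of sigma(eps) and E (eps - offset)
    yield_strength = None
    flagged = False
    if modulus > 0:
        gap = sig - modulus * (eps - offset)
        crossings = np.flatnonzero((gap[:-1] > 0) & (gap[1:] <= 0))
        if crossings.size:
            i = int(crossings[0])
            t = gap[i] / (gap[i] - gap[i + 1])
            yield_strength = float(sig[i] + t * (sig[i + 1] - sig[i]))
    if yield_strength is None:
        local_max = np.flatnonzero((sig[1:-1] >= sig[:-2])
                                   & (sig[1:-1] >= sig[2:]))
        i = int(local_max[0]) + 1 if local_max.size else int(np.argmax(sig))
        yield_strength = float(sig[i])
        flagged = True

    p_lo, p_hi = plateau_window
    band = (eps >= p_lo) & (eps <= p_hi)
    if band.any():
        plateau = float(sig[band].mean())
    else:
        plateau = float(np.interp(min(p_hi, eps[-1]), eps, sig))

    return MechanicalMetrics(
        ultimate_stress=u, energy_absorption=ea, youngs_modulus=modulus,
        yield_strength=min(yield_strength, u), plateau_stress=plateau,
        ea_truncated=truncated, yield_flagged=flagged)


# ---------------------------------------------------------------------------
# synthetic FEA stand-in
# ---------------------------------------------------------------------------

@dataclass
class ResponseGenConfig:
    """Conditions for the synthetic property generator.

    ``base_strength`` (MPa) is the fully dense reference strength;
    ``density_exponent`` the Gibson-Ashby exponent (1.5: bending-dominated
    sheet lattices).  ``rd_coeff`` maps t * mean(1/L) to RD percent per
    surface family; ``savr_cell_mod`` modulates the 2/t SA/VR law with cell
    size.  Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` applied independently per target, unit mean, seeded.
    """

    base_strength: float = 1400.0
    density_exponent: float = 1.5
    type_strength: dict = field(default_factory=lambda: {
        "gyroid": 1.0, "diamond": 1.1, "split_p": 0.85})
    type_energy: dict = field(default_factory=lambda: {
        "gyroid": 1.0, "diamond": 1.05, "split_p": 0.9})
    rd_coeff: dict = field(default_factory=lambda: {
        "gyroid": 2.2, "diamond": 2.5, "split_p": 2.8})
    plateau_fraction: float = 0.75
    elastic_strain: float = 0.02
    rotation_sensitivity: float = 0.05
    aspect_sensitivity: float = 0.03
    savr_cell_mod: float = 0.1
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_strength <= 0 or self.density_exponent <= 0:
            raise ValueError("base_strength and density_exponent must be > 0")
        if not 0 < self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def synthetic_descriptors(df: pd.DataFrame,
                          config: ResponseGenConfig) -> pd.DataFrame:
    """Noise-free analytic RD (%) and SA/VR (1/mm) for a design frame."""
    inv_l = (1.0 / df[["cell_size_x", "cell_size_y", "cell_size_z"]]
             .to_numpy(dtype=float)).mean(axis=1)
    t = df["thickness"].to_numpy(dtype=float)
    coeff = df["surface_type"].map(config.rd_coeff).to_numpy(dtype=float)
    rd = np.minimum(100.0 * coeff * t * inv_l, 95.0)
    cell_factor = 3.5 * inv_l  # 1 at the grid's central 3.5 mm cell
    savr = (2.0 / t) * (1.0 - config.savr_cell_mod
                        + config.savr_cell_mod * cell_factor)
    return pd.DataFrame({"rd_pct": rd, "savr_per_mm": savr}, index=df.index)


def generate_synthetic_properties(df: pd.DataFrame,
                                  config: ResponseGenConfig) -> pd.DataFrame:
    """Synthetic ultimate stress (MPa) and energy absorption (MJ/m^3).

    ``df`` must carry the design columns plus an ``rd_pct`` column (from
    :func:`synthetic_descriptors` or measured descriptors).  Deterministic
    given ``config.seed``.
    """
    if "rd_pct" not in df.columns:
        missing = df.index.tolist()
        raise ValueError(f"rd_pct missing for rows {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    rng = np.random.default_rng(config.seed)
    rd = df["rd_pct"].to_numpy(dtype=float)
    k_u = df["surface_type"].map(config.type_strength).to_numpy(dtype=float)
    k_e = df["surface_type"].map(config.type_energy).to_numpy(dtype=float)
    rot = df["rotation_deg"].to_numpy(dtype=float)
    aspect = (df["height"].to_numpy(dtype=float)
              / df["diameter"].to_numpy(dtype=float))
    modifier = ((1.0 - config.rotation_sensitivity * rot / 90.0)
                * (1.0 + config.aspect_sensitivity * (aspect - 1.0)))
    u_clean = (k_u * config.base_strength * (rd / 100.0)
               ** config.density_exponent * modifier)
    # bilinear curve: linear rise to the plateau stress at elastic_strain,
    # then constant plateau to strain 0.5
    plateau = config.plateau_fraction * u_clean
    ea_clean = k_e * plateau * (0.5 - config.elastic_strain / 2.0)
    u = u_clean * _lognormal_noise(rng, config.noise_cv, len(df))
    ea = ea_clean * _lognormal_noise(rng, config.noise_cv, len(df))
    return pd.DataFrame({"u_mpa": u, "ea_mj_m3": ea}, index=df.index)


def build_synthetic_dataset(designs, config: ResponseGenConfig) -> pd.DataFrame:
    """Design frame + size class + all four synthetic targets.

    RD and SA/VR receive the same multiplicative measurement noise as the
    mechanical targets (independent draws, same cv, one seed stream).
    """
    df = designs if isinstance(designs, pd.DataFrame) else designs_to_frame(designs)
    df = df.copy()
    if "size_class" not in df.columns:
        df["size_class"] = [
            classify_size(LatticeDesign(**{k: row[k] for k in
                                           ("surface_type", "cell_size_x",
                                            "cell_size_y", "cell_size_z",
                                            "thickness", "rotation_deg",
                                            "height", "diameter")}))
            for _, row in df.iterrows()]
    desc = synthetic_descriptors(df, config)
    df["rd_pct"] = desc["rd_pct"]
    mech = generate_synthetic_properties(df, config)
    rng = np.random.default_rng(config.seed + 1)
    df["rd_pct"] = desc["rd_pct"] * _lognormal_noise(rng, config.noise_cv, len(df))
    df["savr_per_mm"] = (desc["savr_per_mm"]
                         * _lognormal_noise(rng, config.noise_cv, len(df)))
    df["u_mpa"] = mech["u_mpa"]
    df["ea_mj_m3"] = mech["ea_mj_m3"]
    return df


__all__ = [
    "TI6AL4V", "JCDamageParams", "jc_failure_strain", "StressStrainCurve",
    "MechanicalMetrics", "to_engineering_curve", "ultimate_stress",
    "energy_absorption", "extended_metrics", "ResponseGenConfig",
    "synthetic_descriptors", "generate_synthetic_properties",
    "build_synthetic_dataset",
]
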