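"""Tip-to-base water potential gradient and conduit-wall collapse limits.

The hydraulic path is modelled as a series of vertically stacked pipe
segments that widen from the leaf tip to the tree base following
``d = d0 * L**alpha``. Each 100 um segment contributes a Hagen-Poiseuille
resistance r = 128*eta*dl / (pi*d^4); total flow follows Darcy's law
Q = (psi_soil - psi_leaf) / R, and the water potential profile is the
cumulative sum psi_i = psi_leaf + Q * sum(r_j, j <= i), anchored at the leaf
boundary psi = psi_leaf and recovering psi_soil at the base identically.

Sap tension P = |psi| sets the critical thickness-to-span ratio at which a
conduit wall, treated as a rectangular plate supported on four edges, fails
in bending: (t/b)^2_crit = P * beta / sigma, with bending coefficient
beta ~= 0.25 and modulus of rupture sigma of green cell-wall material.
Safety factors compare each measured conduit's (t/b)^2 to the critical value
at its own relative path position.

A key property used throughout the tests: psi and (t/b)^2_crit are invariant
to rescaling d0 or eta, because both enter Q and the cumulative resistance as
a single common factor that cancels.

Units: lengths m, diameters um, pressures MPa, viscosity MPa*s, resistance
MPa*s*m^-3. The gravitational pressure head (~0.01 MPa/m) is excluded, being
small for the tree heights considered; the config exposes a hook that only
accepts the excluded setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CollapseConfig",
    "PathProfile",
    "SafetyAssessment",
    "build_path_profile",
    "segment_resistances",
    "water_potential_profile",
    "critical_limit_profile",
    "simulate_profile",
    "safety_factors",
    "assess_by_tree",
    "species_specific_limits",
]


@dataclass(frozen=True)
class CollapseConfig:
    """Parameters of the soil-plant-atmosphere collapse simulation.

    Defaults: a 30 m path in 100 um increments, path exponent 0.23, sap
    viscosity 1.002e-9 MPa*s (water at 20 C), leaf water potential -4.7 MPa
    (the species-minimum midday value), soil water potential -1.5 MPa (a
    typical wilting point), plate bending coefficient 0.25, and a 41.6 MPa
    mean modulus of rupture for green conifer cell-wall material.
    """

    H: float = 30.0
    delta_l: float = 1e-4
    alpha: float = 0.23
    d0: float = 6.0
    eta: float = 1.002e-9
    psi_leaf: float = -4.7
    psi_soil: float = -1.5
    beta_bend: float = 0.25
    sigma_rupture: float = 41.6
    species_sigma: dict | None = None
    gravity_head: float | None = None  # excluded from the model

    def validate(self) -> None:
        if not (self.psi_leaf < self.psi_soil <= 0):
            raise ValueError("require psi_leaf < psi_soil <= 0")
        if self.delta_l <= 0 or self.H / self.delta_l < 10:
            raise ValueError("require delta_l > 0 and H/delta_l >= 10")
        if not (0 < self.beta_bend <= 0.5):
            raise ValueError("beta_bend must lie in (0, 0.5]")
        if self.sigma_rupture <= 0:
            raise ValueError("sigma_rupture must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0 (0 is the uniform-pipe model)")
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.gravity_head not in (None, 0, 0.0):
            raise NotImplementedError(
                "the gravitational pressure head is excluded from this model")


@dataclass
class PathProfile:
    """Discretized tip-to-base hydraulic path.

    Segment arrays (length N, tip-indexed): midpoint position ``L_mid``,
    diameter ``d_um``, resistance ``r``. Node arrays (length N+1, from the
    leaf boundary at L = 0 to the base at L = H): ``L_node``, ``psi``,
    tension ``P``, and ``tb2_crit``. ``psi[0]`` is the leaf boundary value
    psi_leaf; ``psi[i]`` (i >= 1) is the potential at the proximal end of
    segment i.
    """

    config: CollapseConfig
    L_mid: np.ndarray
    d_um: np.ndarray
    r: np.ndarray | None = None
    R: float | None = None
    Q: float | None = None
    psi: np.ndarray | None = None
    P: np.ndarray | None = None
    tb2_crit: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return self.L_mid.size

    @property
    def L_node(self) -> np.ndarray:
        return np.arange(self.n_segments + 1) * self.config.delta_l

    @property
    def L_rel_node(self) -> np.ndarray:
        return self.L_node / (self.n_segments * self.config.delta_l)

    def to_frame(self) -> pd.DataFrame:
        """Node-level CSV-ready table (segment index 0 = leaf boundary)."""
        n = self.n_segments
        return pd.DataFrame({
            "segment_index": np.arange(n + 1),
            "L_m": self.L_node,
            "L_rel": self.L_rel_node,
            "d_um": np.concatenate([[np.nan], self.d_um]),
            "r_MPa_s_m3": np.concatenate([[np.nan], self.r]),
            "psi_MPa": self.psi,
            "P_MPa": self.P,
            "tb2_crit": self.tb2_crit,
        })


def build_path_profile(config: CollapseConfig) -> PathProfile:
    """Segment diameters d_i = d0 * L_mid^alpha on the midpoint grid.

    Midpoint evaluation (L_mid = (i - 1/2) * delta_l) avoids the d(0) = 0
    singularity at the leaf tip; for alpha = 0 the profile degenerates to the
    uniform pipe model.
    """
    config.validate()
    N = int(round(config.H / config.delta_l))
    L_mid = (np.arange(N) + 0.5) * config.delta_l
    d_um = config.d0 * L_mid**config.alpha
    return PathProfile(config, L_mid, d_um)


def segment_resistances(profile: PathProfile) -> PathProfile:
    """Hagen-Poiseuille resistance of each segment (diameter um -> m)."""
    cfg = profile.config
    if np.any(profile.d_um <= 0):
        raise ValueError("segment diameters must be strictly positive")
    d_m = profile.d_um * 1e-6
    profile.r = 128.0 * cfg.eta * cfg.delta_l / (np.pi * d_m**4)
    return profile


def water_potential_profile(profile: PathProfile) -> PathProfile:
    """Darcy flow and the cumulative water potential profile.

    R = sum(r_i); Q = (psi_soil - psi_leaf)/R; psi at the proximal end of
    segment i is psi_leaf + Q * cumulative resistance, so the base recovers
    psi_soil exactly and psi is monotone non-decreasing tip to base.
    """
    if profile.r is None:
        raise ValueError("segment resistances missing; call segment_resistances")
    cfg = profile.config
    R = float(profile.r.sum())
    if R == 0:
        raise ValueError("total resistance is zero")
    Q = (cfg.psi_soil - cfg.psi_leaf) / R
    cum = np.concatenate([[0.0], np.cumsum(profile.r)])
    profile.R, profile.Q = R, Q
    profile.psi = cfg.psi_leaf + Q * cum
    profile.P = np.abs(profile.psi)
    return profile


def critical_limit_profile(profile: PathProfile) -> PathProfile:
    """(t/b)^2_crit = P * beta / sigma at every node.

    With the default potentials this runs from |psi_leaf|*beta/sigma ~= 0.028
    at the leaf boundary down to |psi_soil|*beta/sigma ~= 0.009 at the base.
    """
    if profile.P is None:
        raise ValueError("tensions missing; call water_potential_profile")
    cfg = profile.config
    profile.tb2_crit = profile.P * cfg.beta_bend / cfg.sigma_rupture
    return profile


def simulate_profile(config: CollapseConfig) -> PathProfile:
    """Full pipeline: diameters -> resistances -> potentials -> limits."""
    return critical_limit_profile(
        water_potential_profile(segment_resistances(build_path_profile(config))))


@dataclass(frozen=True)
class SafetyAssessment:
    """Per-conduit safety factors with overall and grouped summaries.

    safety_factor = observed (t/b)^2 / (t/b)^2_crit at the conduit's relative
    path position; a conduit is flagged for collapse when the factor is
    strictly below 1 (equality counts as safe).
    """

    safety_factor: np.ndarray = field(repr=False)
    collapse_flag: np.ndarray = field(repr=False)
    fraction_safe: float
    median_sf: float
    iqr: tuple[float, float]
    by_wood_type: dict
    by_organ: dict

    @property
    def fraction_collapsed(self) -> float:
        return 1.0 - self.fraction_safe

    def to_dict(self) -> dict:
        return {
            "n": int(self.safety_factor.size),
            "fraction_safe": self.fraction_safe,
            "fraction_collapsed": self.fraction_collapsed,
            "median_safety_factor": self.median_sf,
            "iqr": list(self.iqr),
            "by_wood_type": self.by_wood_type,
            "by_organ": self.by_organ,
        }


def _summaries(sf: np.ndarray, flags: np.ndarray, groups: pd.Series):
    out = {}
    for g, idx in groups.groupby(groups, observed=True).groups.items():
        pos = groups.index.get_indexer(idx)
        s = sf[pos]
        out[str(g)] = {
            "n": int(s.size),
            "n_collapsed": int(flags[pos].sum()),
            "median_safety_factor": float(np.median(s)),
        }
    return out


def safety_factors(records: pd.DataFrame, profile: PathProfile
                   ) -> SafetyAssessment:
    """Assess conduits against one simulated profile.

    Records need ``tb2`` and ``L_rel`` columns (see anatomy.conduit_metrics);
    the critical limit is looked up at the nearest node in relative path
    position.
    """
    L_rel = records["L_rel"].to_numpy(float)
    if np.any((L_rel < 0) | (L_rel > 1)):
        raise ValueError("conduit L_rel outside [0, 1]")
    tb2 = records["tb2"].to_numpy(float)
    n = profile.n_segments
    node = np.rint(L_rel * n).astype(int)
    crit = profile.tb2_crit[node]
    sf = tb2 / crit
    flags = sf < 1.0
    q25, q75 = np.percentile(sf, [25, 75])
    return SafetyAssessment(
        sf, flags,
        fraction_safe=float(1.0 - flags.mean()),
        median_sf=float(np.median(sf)),
        iqr=(float(q25), float(q75)),
        by_wood_type=_summaries(sf, flags, records["wood_type"].astype(str))
        if "wood_type" in records else {},
        by_organ=_summaries(sf, flags, records["organ"])
        if "organ" in records else {},
    )


def assess_by_tree(records: pd.DataFrame, config: CollapseConfig
                   ) -> SafetyAssessment:
    """Assess conduits with each conduit's own tree height H.

    One profile is simulated per distinct H (H_m column) and conduits are
    compared against the profile of their own tree.
    """
    sf = np.empty(len(records))
    flags = np.zeros(len(records), bool)
    for H, sub in records.groupby("H_m", observed=True):
        prof = simulate_profile(replace(config, H=float(H)))
        a = safety_factors(sub, prof)
        pos = records.index.get_indexer(sub.index)
        sf[pos] = a.safety_factor
        flags[pos] = a.collapse_flag
    q25, q75 = np.percentile(sf, [25, 75])
    return SafetyAssessment(
        sf, flags,
        fraction_safe=float(1.0 - flags.mean()),
        median_sf=float(np.median(sf)),
        iqr=(float(q25), float(q75)),
        by_wood_type=_summaries(sf, flags, records["wood_type"].astype(str))
        if "wood_type" in records else {},
        by_organ=_summaries(sf, flags, records["organ"])
        if "organ" in records else {},
    )


def species_specific_limits(records: pd.DataFrame, config: CollapseConfig
                            ) -> dict[str, SafetyAssessment]:
    """Per-species assessments using each species' modulus of rupture.

    (t/b)^2_crit is inversely proportional to sigma, so halving a species'
    sigma exactly doubles its critical limit everywhere.
    """
    if config.species_sigma is None:
        raise ValueError("config.species_sigma is required")
    present = records["species"].astype(str).unique()
    missing = [s for s in present if s not in config.species_sigma]
    if missing:
        raise ValueError(f"missing modulus of rupture for species: {missing}")
    out = {}
    for sp in present:
        sub = records[records["species"].astype(str) == sp]
        cfg = replace(config, sigma_rupture=float(config.species_sigma[sp]))
        out[sp] = assess_by_tree(sub, cfg)
    return out
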