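"""Synthetic conduit-table generator.

Emulates the statistical structure of conifer quantitative-wood-anatomy
datasets sampled along the full hydraulic path (leaves to very fine roots):

* lumen diameters log-normally scattered around a tip-to-base widening power
  law ``d = d0 * L**alpha`` (shoots) and ``d = d0 * D**beta`` (roots),
* strongly unbalanced conduit counts across path-length / organ-diameter
  bins (more conduits measured where organs are thicker),
* thickness-to-span ratios decaying exponentially in relative path position
  ``L/H`` with multiplicative noise,
* an earlywood/latewood mixture with latewood reinforcement,
* organ external diameters tied to path length by a power law.

Every downstream stage of the analysis (anatomy metrics, bin-balanced Model II
fits, the collapse model) is testable against the generator's known truths.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ORGANS",
    "SHOOT_ORGANS",
    "STEM_ORGANS",
    "ROOT_ORGANS",
    "COLUMNS",
    "CountModel",
    "GeneratorConfig",
    "GeneratorConfigError",
    "TableValidationError",
    "generate_dataset",
    "write_table",
    "read_table",
    "validate_table",
]

#: Organ vocabulary in axial order, leaf (1) -> very fine root (7).
ORGANS = (
    "leaf",
    "twig",
    "branch",
    "trunk",
    "coarse_root",
    "fine_root",
    "very_fine_root",
)

#: Organs whose conduits enter the d-versus-L (path length) fits.
SHOOT_ORGANS = ("leaf", "twig", "branch", "trunk")

#: Aboveground organs with an external diameter (d-versus-D stem fits).
STEM_ORGANS = ("twig", "branch", "trunk")

#: Belowground organs; fitted against external root diameter only.
ROOT_ORGANS = ("coarse_root", "fine_root", "very_fine_root")

#: Canonical CSV column order.
COLUMNS = [
    "species",
    "tree_id",
    "organ",
    "sample_id",
    "L_m",
    "H_m",
    "D_mm",
    "d_um",
    "d_rad_um",
    "wall_rad1_um",
    "wall_rad2_um",
    "wall_tan1_um",
    "wall_tan2_um",
    "wood_type",
]

_MANDATORY = [c for c in COLUMNS if c != "wood_type"]
_NUMERIC = [
    "L_m", "H_m", "D_mm", "d_um", "d_rad_um",
    "wall_rad1_um", "wall_rad2_um", "wall_tan1_um", "wall_tan2_um",
]


class GeneratorConfigError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


class TableValidationError(ValueError):
    """Raised when a conduit table violates the schema; carries row indices."""

    def __init__(self, findings):
        self.findings = list(findings)
        msg = "; ".join(f"row {r}: {m}" if r is not None else m
                        for r, m in self.findings[:20])
        if len(self.findings) > 20:
            msg += f" (+{len(self.findings) - 20} more)"
        super().__init__(msg)


@dataclass(frozen=True)
class CountModel:
    """Rule mapping organ external diameter to the number of conduits sampled.

    Conduits per sample grow with the organ's cross-sectional area
    (``per_mm2 * D**2``), clipped to [min_count, max_count]; organs without an
    external diameter (leaves) draw uniformly from ``leaf_range``. This
    reproduces the order-of-magnitude bin imbalance that the balanced
    resampling procedure exists to correct.
    """

    per_mm2: float = 1.0
    min_count: int = 20
    max_count: int = 5000
    leaf_range: tuple[int, int] = (20, 100)

    def draw(self, D_mm: float | None, rng: np.random.Generator) -> int:
        if D_mm is None or not np.isfinite(D_mm):
            lo, hi = self.leaf_range
            return int(rng.integers(lo, hi + 1))
        n = int(round(self.per_mm2 * D_mm**2))
        return int(np.clip(n, self.min_count, self.max_count))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic conduit generator.

    Scaling truths default to the exponents the analysis is designed around
    (path exponent 0.23; stem and root diameter exponents 0.32 and 0.42), the
    latewood share to 0.81, and the thickness-to-span decay to
    ``0.8 * exp(-1.5 * L/H)``.
    """

    n_species: int = 5
    n_trees_per_species: int = 5
    height_range: tuple[float, float] = (15.0, 45.0)

    # d = d0_true * L**alpha_true for shoot organs (d in um, L in m)
    alpha_true: float = 0.23
    d0_true: float = 6.0
    sigma_log_d: float = 0.05  # sd of log10 d around the law

    # d = d0_root_true * D**beta_root_true for root organs (D in mm)
    beta_root_true: float = 0.42
    d0_root_true: float = 2.19

    # (t/b)^2 target = tb2_intercept * exp(-tb2_decay_rate * L/H)
    tb2_intercept: float = 0.8
    tb2_decay_rate: float = 1.5
    sigma_log_tb2: float = 0.15  # sd of log10 (t/b)^2 around the law

    latewood_fraction: float = 0.81
    latewood_tb2_multiplier: float = 3.0

    # L ∝ D**stem_length_diameter_exponent; with the path law this embeds a
    # stem diameter-scaling exponent beta_stem_true = alpha_true * exponent.
    stem_length_diameter_exponent: float = 1.391
    stem_diameter_norm: float = 5.0  # mm at L = 1 m

    count_model: CountModel = field(default_factory=CountModel)

    # samples per tree, by organ
    samples_per_organ: dict = field(default_factory=lambda: {
        "leaf": 5, "twig": 3, "branch": 1, "trunk": 1,
        "coarse_root": 2, "fine_root": 3, "very_fine_root": 2,
    })

    seed: int = 0

    @property
    def beta_stem_true(self) -> float:
        """Stem diameter-scaling exponent implied by the path and D-L laws."""
        return self.alpha_true * self.stem_length_diameter_exponent

    def validate(self) -> None:
        lo, hi = self.height_range
        if not (0 < lo <= hi):
            raise GeneratorConfigError("heights must be strictly positive")
        if self.alpha_true <= 0 or self.d0_true <= 0:
            raise GeneratorConfigError("alpha_true and d0_true must be > 0")
        if self.beta_root_true <= 0 or self.d0_root_true <= 0:
            raise GeneratorConfigError("root scaling parameters must be > 0")
        if not 0 <= self.latewood_fraction <= 1:
            raise GeneratorConfigError("latewood_fraction must be in [0, 1]")
        if min(self.sigma_log_d, self.sigma_log_tb2) < 0:
            raise GeneratorConfigError("noise sds must be >= 0")
        if self.latewood_tb2_multiplier < 1:
            raise GeneratorConfigError("latewood_tb2_multiplier must be >= 1")
        if self.tb2_intercept <= 0:
            raise GeneratorConfigError("tb2_intercept must be > 0")
        # extreme decay rates produce non-finite wall targets
        peak = self.tb2_intercept * np.exp(max(0.0, -self.tb2_decay_rate))
        if not np.isfinite(peak):
            raise GeneratorConfigError("tb2 law produces non-finite targets")
        if self.stem_length_diameter_exponent <= 0:
            raise GeneratorConfigError("stem_length_diameter_exponent must be > 0")


# L windows for shoot organ placement (m); trunk is sampled at the tree base
# (L = H) and roots are assigned L = H (never beyond: 0 < L <= H).
_ORGAN_L_WINDOWS = {
    "leaf": (0.002, 0.05),
    "twig": (0.05, 0.3),
    "branch": (0.3, 1.2),
}

# external diameter windows for root organs (mm), sampled log-uniformly
_ROOT_D_WINDOWS = {
    "coarse_root": (3.0, 50.0),
    "fine_root": (1.0, 3.0),
    "very_fine_root": (0.2, 1.0),
}


def _stem_D(cfg: GeneratorConfig, L: float) -> float:
    """Organ external diameter (mm) of an aboveground axis at path length L."""
    return cfg.stem_diameter_norm * L ** (1.0 / cfg.stem_length_diameter_exponent)


def _sample_conduits(cfg, rng, species, tree_id, organ, sample_id, L, H, D_mm):
    """Draw one tissue sample's worth of conduit rows."""
    n = cfg.count_model.draw(D_mm, rng)

    if organ in ROOT_ORGANS:
        log_med = np.log10(cfg.d0_root_true) + cfg.beta_root_true * np.log10(D_mm)
    else:
        log_med = np.log10(cfg.d0_true) + cfg.alpha_true * np.log10(L)
    d = 10.0 ** (log_med + rng.normal(0.0, cfg.sigma_log_d, n))

    tb2 = (cfg.tb2_intercept
           * np.exp(-cfg.tb2_decay_rate * L / H)
           * 10.0 ** rng.normal(0.0, cfg.sigma_log_tb2, n))
    latewood = rng.random(n) < cfg.latewood_fraction
    tb2 = np.where(latewood, tb2 * cfg.latewood_tb2_multiplier, tb2)

    # wall synthesis: span b = lumen diameter d, double wall t = b*sqrt(tb2);
    # tangential single walls t/2 (the deterministic minimum), radial walls
    # 10-15% thicker so the tangential wall always drives (t/b)^2.
    t = d * np.sqrt(tb2)
    x_tan = t / 2.0
    wall_rad1 = 1.10 * x_tan
    wall_rad2 = 1.15 * x_tan

    # radial lumen diameter chosen so Mork's index M = 4*x_tan/d_rad agrees
    # with the drawn wood-type label (latewood iff M > 1)
    M = np.where(latewood, rng.uniform(1.05, 3.0, n), rng.uniform(0.2, 1.0, n))
    d_rad = 4.0 * x_tan / M

    bad = ~(np.isfinite(d) & (d > 0) & np.isfinite(tb2) & (tb2 > 0)
            & np.isfinite(d_rad) & (d_rad > 0))
    if bad.any():  # pragma: no cover - lognormal draws are positive
        keep = ~bad
        d, x_tan, wall_rad1 = d[keep], x_tan[keep], wall_rad1[keep]
        wall_rad2, d_rad, latewood = wall_rad2[keep], d_rad[keep], latewood[keep]
        n = keep.sum()

    return pd.DataFrame({
        "species": species,
        "tree_id": tree_id,
        "organ": organ,
        "sample_id": sample_id,
        "L_m": L,
        "H_m": H,
        "D_mm": np.nan if D_mm is None else D_mm,
        "d_um": d,
        "d_rad_um": d_rad,
        "wall_rad1_um": wall_rad1,
        "wall_rad2_um": wall_rad2,
        "wall_tan1_um": x_tan,
        "wall_tan2_um": x_tan,
        "wood_type": np.where(latewood, "latewood", "earlywood"),
    })


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a conduit-level dataset with the configured structure.

    One root seed deterministically spawns per-tree substreams, so the same
    ``(config, seed)`` always yields a byte-identical table and regenerating
    a subset of trees does not disturb the others.
    """
    config.validate()
    cfg = config
    root_ss = np.random.SeedSequence(cfg.seed)
    n_trees = cfg.n_species * cfg.n_trees_per_species
    streams = root_ss.spawn(n_trees)

    frames = []
    k = 0
    for s in range(cfg.n_species):
        species = f"species_{s + 1:02d}"
        for t in range(cfg.n_trees_per_species):
            rng = np.random.default_rng(streams[k])
            k += 1
            tree_id = f"{species}_tree_{t + 1:02d}"
            H = float(rng.uniform(*cfg.height_range))
            sample_no = 0
            for organ in ORGANS:
                for _ in range(cfg.samples_per_organ.get(organ, 0)):
                    sample_no += 1
                    sample_id = f"{tree_id}_s{sample_no:02d}"
                    if organ in _ORGAN_L_WINDOWS:
                        lo, hi = _ORGAN_L_WINDOWS[organ]
                        L = float(rng.uniform(lo, hi))
                        D = None if organ == "leaf" else _stem_D(cfg, L)
                    elif organ == "trunk":
                        L = H
                        D = _stem_D(cfg, L)
                    else:  # roots: own D, positioned at the base of the path
                        lo, hi = _ROOT_D_WINDOWS[organ]
                        D = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
                        L = H
                    frames.append(_sample_conduits(
                        cfg, rng, species, tree_id, organ, sample_id, L, H, D))

    df = pd.concat(frames, ignore_index=True)
    df["organ"] = pd.Categorical(df["organ"], categories=ORGANS, ordered=True)
    return df


def write_table(records: pd.DataFrame, path) -> None:
    """Write a conduit table as UTF-8 CSV with the documented column schema."""
    cols = [c for c in COLUMNS if c in records.columns]
    extras = [c for c in records.columns if c not in cols]
    records[cols + extras].to_csv(path, index=False, encoding="utf-8")


def validate_table(df: pd.DataFrame) -> list[tuple[int | None, str]]:
    """Return (row_index, message) findings; empty list means a clean table."""
    findings: list[tuple[int | None, str]] = []
    for col in _MANDATORY:
        if col not in df.columns:
            findings.append((None, f"missing mandatory column {col!r}"))
    if findings:
        return findings

    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        for idx in df.index[bad]:
            findings.append((int(idx), f"non-numeric value in {col!r}"))

    num = df[_NUMERIC].apply(pd.to_numeric, errors="coerce")
    strict_pos = ["L_m", "H_m", "d_um", "d_rad_um",
                  "wall_rad1_um", "wall_rad2_um", "wall_tan1_um", "wall_tan2_um"]
    for col in strict_pos:
        bad = num[col].notna() & (num[col] <= 0)
        for idx in df.index[bad]:
            findings.append((int(idx), f"non-positive {col!r}"))
    bad = num["D_mm"].notna() & (num["D_mm"] <= 0)
    for idx in df.index[bad]:
        findings.append((int(idx), "non-positive 'D_mm'"))

    bad = num["L_m"].notna() & num["H_m"].notna() & (num["L_m"] > num["H_m"])
    for idx in df.index[bad]:
        findings.append((int(idx), "L_m exceeds H_m"))

    bad = ~df["organ"].astype(str).isin(ORGANS)
    for idx in df.index[bad]:
        findings.append((int(idx), f"unknown organ {df.loc[idx, 'organ']!r}"))

    if "wood_type" in df.columns:
        ok = df["wood_type"].isna() | df["wood_type"].astype(str).isin(
            ["earlywood", "latewood"])
        for idx in df.index[~ok]:
            findings.append((int(idx), f"unknown wood_type {df.loc[idx, 'wood_type']!r}"))
    return sorted(findings, key=lambda f: (f[0] is None, f[0]))


def read_table(path) -> pd.DataFrame:
    """Read and validate a conduit CSV.

    Headers are matched case-insensitively and normalized to the canonical
    schema; unknown extra columns are preserved untouched as opaque metadata.
    A missing ``wood_type`` column is recomputed downstream via Mork's index.
    Raises :class:`TableValidationError` with row indices on invalid data.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        df = pd.read_csv(path)
    else:  # file-like
        df = pd.read_csv(_io.TextIOWrapper(path) if isinstance(path, _io.BufferedReader) else path)
    canon = {c.lower(): c for c in COLUMNS}
    df = df.rename(columns={c: canon[c.lower()] for c in df.columns
                            if c.lower() in canon})
    findings = validate_table(df)
    if findings:
        raise TableValidationError(findings)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col])
    df["organ"] = pd.Categorical(df["organ"].astype(str),
                                 categories=ORGANS, ordered=True)
    return df


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``config`` with all multiplicative noise switched off."""
    return replace(config, sigma_log_d=0.0, sigma_log_tb2=0.0)
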