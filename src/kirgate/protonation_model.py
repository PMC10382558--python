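"""Equilibrium protonation model of Kir2 sub-conductance gating.

A Kir2 channel is a homotetramer.  When an acidic side chain is introduced
near the helix bundle crossing, each of the four subunits carries an
independently titratable site.  The model assumes

* each site binds a proton independently (no cooperativity) with a common
  dissociation constant ``K_H`` (molar; pKa = -log10 K_H),
* channel conductance decreases with the total number ``k`` of protonated
  subunits, giving one open level per ``k``,
* every open level exchanges with a paired brief-closed level with a
  dimensionless equilibrium constant ``K_OC`` (closed/open), independent of
  protonation.

With ``N`` sites and proton occupancy fraction ``f(pH)``, the protonation
count is binomial, the open/closed split is ``1/(1+K_OC)`` vs
``K_OC/(1+K_OC)``, and the occupancy of every level follows analytically.
A generalization to several site classes (e.g. engineered tandem dimers
with fewer ionizable subunits, or additional cavity aspartates) takes the
convolution of per-class binomials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass(frozen=True)
class SiteClass:
    """One class of titratable sites.

    Parameters
    ----------
    label:
        Short identifier, e.g. ``"HBC-D"`` for the engineered aspartate at
        the helix bundle crossing or ``"cavity-D"`` for the native cavity
        aspartate.
    n_sites:
        Number of sites of this class per channel (4 in the homotetramer;
        2 in a tandem-dimer construct with two ionizable subunits).
    K_H:
        Proton dissociation constant in mol/L.  ``pKa = -log10(K_H)``.
    """

    label: str
    n_sites: int
    K_H: float

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError(f"n_sites must be >= 0, got {self.n_sites}")
        if not (self.K_H > 0):
            raise ValueError(f"K_H must be > 0, got {self.K_H}")


def _default_conductance_map(n_total: int) -> dict[int, float]:
    # Non-increasing relative conductance with k = number of protonated
    # sites.  For the tetramer the four resolvable levels carry amplitudes
    # 1.00/0.92/0.74/0.45; the two least-protonated states are not
    # experimentally distinguishable and share the top amplitude.
    if n_total == 4:
        return {0: 1.0, 1: 1.0, 2: 0.92, 3: 0.74, 4: 0.45}
    if n_total == 0:
        return {0: 1.0}
    ks = np.arange(n_total + 1)
    vals = 1.0 - 0.8 * ks / n_total
    return {int(k): float(v) for k, v in zip(ks, vals)}


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the gating model.

    ``conductance_map`` maps total protonation count ``k`` to relative
    conductance in [0, 1] (non-increasing, ``conductance_map[0] == 1``).
    ``K_OC`` is the open <-> brief-closed equilibrium constant.
    """

    site_classes: tuple[SiteClass, ...]
    K_OC: float = 0.05
    conductance_map: dict[int, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_classes", tuple(self.site_classes))
        if self.K_OC < 0:
            raise ValueError(f"K_OC must be >= 0, got {self.K_OC}")
        n = self.n_total
        cmap = self.conductance_map
        if cmap is None:
            cmap = _default_conductance_map(n)
        cmap = {int(k): float(v) for k, v in cmap.items()}
        missing = [k for k in range(n + 1) if k not in cmap]
        if missing:
            raise ValueError(f"conductance_map missing k = {missing}")
        vals = [cmap[k] for k in range(n + 1)]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("conductance_map must be non-increasing in k")
        object.__setattr__(self, "conductance_map", cmap)

    @property
    def n_total(self) -> int:
        """Total number of titratable sites across classes."""
        return sum(c.n_sites for c in self.site_classes)

    @classmethod
    def single_class(cls, n_sites: int = 4, K_H: float = 2e-7,
                     K_OC: float = 0.05,
                     conductance_map: dict[int, float] | None = None,
                     label: str = "HBC-D") -> "ModelParams":
        """Convenience constructor for the homotetramer one-class model."""
        return cls(site_classes=(SiteClass(label, n_sites, K_H),),
                   K_OC=K_OC, conductance_map=conductance_map)

    # -- config round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "site_classes": [
                {"label": c.label, "n_sites": c.n_sites, "K_H": c.K_H}
                for c in self.site_classes
            ],
            "K_OC": self.K_OC,
            "conductance_map": {str(k): v
                                for k, v in self.conductance_map.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        classes = tuple(SiteClass(c["label"], int(c["n_sites"]),
                                  float(c["K_H"]))
                        for c in d["site_classes"])
        cmap = d.get("conductance_map")
        if cmap is not None:
            cmap = {int(k): float(v) for k, v in cmap.items()}
        return cls(site_classes=classes, K_OC=float(d["K_OC"]),
                   conductance_map=cmap)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class StateDistribution:
    """Equilibrium probabilities over model states at one pH.

    ``p_open[k]`` / ``p_closed[k]`` are the probabilities of the open and
    brief-closed state with ``k`` protonated sites; together they sum to 1.
    """

    p_open: np.ndarray
    p_closed: np.ndarray
    pH: float

    def __post_init__(self) -> None:
        po = np.asarray(self.p_open, float)
        pc = np.asarray(self.p_closed, float)
        if po.shape != pc.shape:
            raise ValueError("p_open and p_closed must have equal length")
        if (po < -1e-15).any() or (pc < -1e-15).any():
            raise ValueError("negative state probability")
        total = po.sum() + pc.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"state probabilities sum to {total}, not 1")
        object.__setattr__(self, "p_open", po)
        object.__setattr__(self, "p_closed", pc)


class TitrationTable:
    """Occupancy-vs-pH table: one row per pH, columns C, O1..Om.

    O-levels are ordered by increasing conductance, i.e. ``Om`` (the last
    column) is the fully open level.  Occupancies are time-weighted
    probabilities and each row sums to 1.
    """

    def __init__(self, df: pd.DataFrame):
        if "pH" not in df.columns:
            raise ValueError("TitrationTable requires a 'pH' column")
        occ_cols = [c for c in df.columns if c not in ("pH", "weight")]
        if "C" not in occ_cols:
            raise ValueError("TitrationTable requires a 'C' column")
        pH = df["pH"].to_numpy(float)
        if len(pH) > 1 and not (np.diff(pH) > 0).all():
            raise ValueError("pH must be strictly increasing across rows")
        sums = df[occ_cols].to_numpy(float).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each occupancy row must sum to 1 (tol 1e-6)")
        self.df = df.reset_index(drop=True)
        self.level_names = occ_cols

    @property
    def pH(self) -> np.ndarray:
        return self.df["pH"].to_numpy(float)

    @property
    def occupancies(self) -> np.ndarray:
        """(n_rows, n_levels) array in column order ``level_names``."""
        return self.df[self.level_names].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        if "weight" in self.df.columns:
            return self.df["weight"].to_numpy(float)
        return np.ones(len(self.df))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TitrationTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, pH, occupancies, level_names=None,
                    weights=None) -> "TitrationTable":
        occ = np.asarray(occupancies, float)
        if level_names is None:
            level_names = ["C"] + [f"O{i}" for i in range(1, occ.shape[1])]
        data = {"pH": np.asarray(pH, float)}
        for j, name in enumerate(level_names):
            data[name] = occ[:, j]
        if weights is not None:
            data["weight"] = np.asarray(weights, float)
        return cls(pd.DataFrame(data))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (f"TitrationTable({len(self)} rows, "
                f"levels={self.level_names})")


# ---------------------------------------------------------------------------
# operations


def site_protonation_fraction(pH: float, K_H: float):
    """Fraction of sites protonated at a given pH.

    ``f = [H+] / ([H+] + K_H)`` with ``[H+] = 10**(-pH)`` mol/L.
    Monotone decreasing in pH; f = 1/2 at pH = pKa = -log10(K_H).
    """
    pH = np.asarray(pH, dtype=float)
    if not np.all(np.isfinite(pH)):
        raise ValueError("pH must be finite")
    if not (K_H > 0):
        raise ValueError(f"K_H must be > 0, got {K_H}")
    h = 10.0 ** (-pH)
    out = h / (h + K_H)
    return float(out) if out.ndim == 0 else out


def _binomial_pmf(n: int, f: float) -> np.ndarray:
    # binomial coefficients are exact for the small n used here
    from scipy.stats import binom
    return binom.pmf(np.arange(n + 1), n, f)


def protonation_count_distribution(params: ModelParams, pH: float) -> np.ndarray:
    """P(k protonated sites) -- convolution of independent per-class binomials."""
    pk = np.array([1.0])
    for c in params.site_classes:
        if c.n_sites == 0:
            continue
        f = site_protonation_fraction(pH, c.K_H)
        pk = np.convolve(pk, _binomial_pmf(c.n_sites, f))
    n = params.n_total
    if len(pk) < n + 1:  # all classes empty
        pk = np.pad(pk, (0, n + 1 - len(pk)))
    return pk


def state_distribution(params: ModelParams, pH: float) -> StateDistribution:
    """Equilibrium distribution over (k, open/closed) states at one pH.

    Sites protonate independently, so the joint count distribution is the
    convolution of per-class binomials; each level splits open vs
    brief-closed as ``1 : K_OC``.
    """
    pk = protonation_count_distribution(params, pH)
    pk = pk / pk.sum()  # guard tiny fp drift so invariant holds to 1e-12
    open_frac = 1.0 / (1.0 + params.K_OC)
    p_open = pk * open_frac
    p_closed = pk - p_open
    return StateDistribution(p_open=p_open, p_closed=p_closed, pH=float(pH))


def default_aggregation(n_total: int) -> dict[int, int]:
    """Default mapping model-k -> experimental open level index.

    Experimental levels are numbered 1..m with m the fully open level.
    For the tetramer (n=4) the two least-protonated open states are merged
    into the top experimental level, leaving four resolvable open levels:
    k=0,1 -> O4; k=2 -> O3; k=3 -> O2; k=4 -> O1.
    """
    if n_total == 0:
        return {0: 1}
    if n_total >= 2:
        # merge k=0 and k=1 into the top level
        m = n_total  # number of experimental open levels
        agg = {0: m, 1: m}
        for k in range(2, n_total + 1):
            agg[k] = n_total + 1 - k
        return agg
    return {0: 1, 1: 1}


def aggregate_levels(dist: StateDistribution,
                     aggregation: dict[int, int] | None = None) -> np.ndarray:
    """Collapse model states to experimental occupancies [C, O1..Om].

    All brief-closed states pool into the single experimental closed level
    C; open states map through ``aggregation`` (model protonation count k
    -> experimental level index, 1-based with m = fully open).
    """
    n = len(dist.p_open) - 1
    if aggregation is None:
        aggregation = default_aggregation(n)
    missing = [k for k in range(n + 1) if k not in aggregation]
    if missing:
        raise ValueError(f"aggregation missing model states k = {missing}")
    m = max(aggregation.values())
    out = np.zeros(m + 1)
    out[0] = dist.p_closed.sum()
    for k in range(n + 1):
        out[aggregation[k]] += dist.p_open[k]
    return out


def predict_titration(params: ModelParams, pH_grid,
                      aggregation: dict[int, int] | None = None,
                      ) -> TitrationTable:
    """Predicted occupancy-vs-pH table on a grid of pH values."""
    pH_grid = np.asarray(pH_grid, float)
    if pH_grid.size < 2:
        raise ValueError("pH grid must have at least 2 points")
    if not np.all(np.isfinite(pH_grid)):
        raise ValueError("pH grid must be finite")
    rows = [aggregate_levels(state_distribution(params, p), aggregation)
            for p in pH_grid]
    return TitrationTable.from_arrays(pH_grid, np.vstack(rows))


@dataclass
class FitResult:
    """Result of a titration fit."""

    params: ModelParams
    converged: bool
    residuals: np.ndarray  # per-row weighted RMS residual
    cost: float
    message: str = ""


def fit_titration(data: TitrationTable, params0: ModelParams,
                  free: tuple[str, ...] = ("K_H", "K_OC"),
                  aggregation: dict[int, int] | None = None) -> FitResult:
    """Fit K_H (per class) and/or K_OC to an occupancy-vs-pH table.

    Minimizes the weighted sum of squared occupancy residuals; parameters
    are optimized on a log10 scale.  ``free`` selects which of
    ``"K_H"`` (all classes' dissociation constants) and ``"K_OC"`` are
    fitted; the rest stay at their ``params0`` values.

    Raises on degenerate data (all rows identical) and on tables with
    fewer rows than free parameters; non-convergence is flagged on the
    result, not silent.
    """
    if not free:
        raise ValueError("no free parameters requested")
    unknown = set(free) - {"K_H", "K_OC"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")

    occ = data.occupancies
    if len(data) > 1 and np.allclose(occ, occ[0], atol=1e-12):
        raise ValueError("degenerate data: all occupancy rows identical")

    n_free = 0
    kh_free = "K_H" in free
    koc_free = "K_OC" in free
    if kh_free:
        n_free += len(params0.site_classes)
    if koc_free:
        n_free += 1
    if len(data) < n_free:
        raise ValueError(
            f"{len(data)} rows cannot constrain {n_free} free parameters")

    w = np.sqrt(data.weights)[:, None]

    def unpack(theta: np.ndarray) -> ModelParams:
        i = 0
        classes = list(params0.site_classes)
        if kh_free:
            classes = [replace(c, K_H=10.0 ** theta[i + j])
                       for j, c in enumerate(classes)]
            i += len(classes)
        koc = params0.K_OC
        if koc_free:
            koc = 10.0 ** theta[i]
        return ModelParams(site_classes=tuple(classes), K_OC=koc,
                           conductance_map=params0.conductance_map)

    def resid(theta: np.ndarray) -> np.ndarray:
        p = unpack(theta)
        pred = predict_titration(p, data.pH, aggregation).occupancies
        return ((pred - occ) * w).ravel()

    theta0 = []
    if kh_free:
        theta0 += [np.log10(c.K_H) for c in params0.site_classes]
    if koc_free:
        theta0.append(np.log10(max(params0.K_OC, 1e-12)))

    sol = optimize.least_squares(resid, np.asarray(theta0), method="lm",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fitted = unpack(sol.x)
    res_rows = resid(sol.x).reshape(len(data), -1)
    per_row = np.sqrt((res_rows ** 2).mean(axis=1))
    return FitResult(params=fitted, converged=bool(sol.success),
                     residuals=per_row, cost=float(sol.cost),
                     message=sol.message)
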