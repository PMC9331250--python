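"""Time-series gene regulatory network inference (GENIE3 family).

Infers a liver-source x aorta-target variable-importance matrix (VIM) under a
first-order decay dynamical model. For each target gene j with decay rate
alpha_j, consecutive-timepoint pairs of the replicate-averaged trajectories
supply training rows

    inputs  = source expression at t_k
    response y_k = (x_j(t_{k+1}) - x_j(t_k)) / (t_{k+1} - t_k) + alpha_j x_j(t_k)

pooled over the diet series (chow and HFD enter as two independent time
series). A randomized regression-tree ensemble is fit per target and the
impurity-reduction importance of each source, normalised to sum one per
target, is that source's edge weight.

With randomized split thresholds (extremely-randomized trees, the default)
the expected impurity reduction of a candidate regulator depends on how its
trajectory's value spacings align with the response — which is what
discriminates regulators when short monotone series would give deterministic
best-split forests identical candidate partitions (and therefore tied
importances). Random forests remain available via ``ensemble="rf"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor

from .deg import size_factors
from .errors import DesignError, MissingGroupError
from .io import CountMatrix, SampleSheet

__all__ = [
    "Trajectory",
    "VimMatrix",
    "build_trajectories",
    "estimate_alpha",
    "TimeSeriesGRN",
    "infer_vim",
]

ALPHA_FLOOR = 1e-2


@dataclass(frozen=True)
class Trajectory:
    """Replicate-summarised log-expression time series for one diet series."""

    tissue: str
    diet: str
    gene_ids: tuple[str, ...]
    times: tuple[int, ...]
    values: np.ndarray  # genes x times

    def __post_init__(self) -> None:
        if len(self.times) < 3:
            raise DesignError("a trajectory needs at least 3 timepoints")
        if list(self.times) != sorted(set(self.times)):
            raise DesignError("trajectory times must be strictly increasing")
        if self.values.shape != (len(self.gene_ids), len(self.times)):
            raise DesignError("trajectory values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DesignError("trajectory contains missing values")

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def build_trajectories(
    counts: CountMatrix,
    sheet: SampleSheet,
    genes: Sequence[str] | None = None,
    tissue: str | None = None,
) -> list[Trajectory]:
    """Per-diet replicate-averaged log trajectories for one tissue.

    Counts are size-factor normalised across the tissue's samples, transformed
    as log(1 + normalised count) per sample, then averaged over the replicates
    of each (diet, timepoint) cell — transform before averaging.
    """
    frame = counts.frame
    if genes is not None:
        missing = set(genes) - set(frame.index)
        if missing:
            raise DesignError(f"requested genes absent from counts: {sorted(missing)}")
        frame = frame.loc[list(genes)]
    sub = sheet.frame[sheet.frame["sample_id"].isin(frame.columns)]
    tissues = sorted(sub["tissue"].unique())
    if tissue is None:
        if len(tissues) != 1:
            raise DesignError(f"counts span tissues {tissues}; pass tissue=")
        tissue = tissues[0]
    sf = size_factors(counts.frame)
    log_norm = np.log1p(frame / sf[frame.columns])
    times = sorted(sub["time_weeks"].unique())
    out = []
    for diet in ("chow", "HFD"):
        cols = []
        for t in times:
            cell = sub[(sub["diet"] == diet) & (sub["time_weeks"] == t)]
            if cell.empty:
                raise MissingGroupError(f"{tissue}: no {diet} samples at t={t}")
            cols.append(log_norm[cell["sample_id"]].mean(axis=1))
        out.append(
            Trajectory(
                tissue=tissue,
                diet=diet,
                gene_ids=tuple(frame.index),
                times=tuple(int(t) for t in times),
                values=np.column_stack(cols),
            )
        )
    return out


def estimate_alpha(
    trajs: "Trajectory | Iterable[Trajectory]",
    gene: str,
    mode: str | float = "from_data",
    floor: float = ALPHA_FLOOR,
) -> float:
    """Per-gene decay rate for the dynamical model.

    ``mode`` may be a fixed positive number, or ``"from_data"``: the log ratio
    of the gene's maximum to minimum trajectory value over the elapsed time
    between them, ln(x_max / x_min) / |t_max - t_min|, computed on the
    shifted-positive trajectory and floored at ``floor``. With several diet
    series the largest per-series estimate is used. Flat trajectories return
    the floor.
    """
    if isinstance(mode, (int, float)):
        value = float(mode)
        if value <= 0:
            raise DesignError("fixed alpha must be positive")
        return value
    if mode != "from_data":
        raise DesignError(f"unknown alpha mode {mode!r}")
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    best = 0.0
    for traj in trajs:
        x = traj.gene(gene).astype(float)
        if x.min() <= 0:
            x = x - x.min() + 1.0  # shift to a positive scale
        i_max, i_min = int(np.argmax(x)), int(np.argmin(x))
        dt = abs(traj.times[i_max] - traj.times[i_min])
        if dt == 0 or x[i_max] == x[i_min]:
            continue
        best = max(best, float(np.log(x[i_max] / x[i_min]) / dt))
    return max(best, floor)


@dataclass(frozen=True)
class VimMatrix:
    """Source x target variable-importance matrix with run metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.frame.to_numpy() < 0).any():
            raise DesignError("VIM entries must be >= 0")

    @property
    def source_genes(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def target_genes(self) -> list[str]:
        return self.frame.columns.tolist()

    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        out = self.frame.copy()
        out.index.name = "source_gene"
        out.to_csv(path, sep="\t")
        if sidecar is not None:
            lines = [f"{k}\t{v}" for k, v in sorted(self.metadata.items())]
            Path(sidecar).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "VimMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def _check_series_compatible(
    source_trajs: Sequence[Trajectory], target_trajs: Sequence[Trajectory]
) -> None:
    if len(source_trajs) != len(target_trajs) or not source_trajs:
        raise DesignError("need matching, non-empty source and target series lists")
    for s, t in zip(source_trajs, target_trajs):
        if s.diet != t.diet:
            raise DesignError("source/target series must be paired by diet")
        if s.times != t.times:
            raise DesignError("source and target series must share time grids")


class TimeSeriesGRN(BaseEstimator):
    """dynGENIE3-style source-to-target network inference.

    scikit-learn style estimator. ``fit(source_trajs, target_trajs)``
    consumes paired per-diet trajectories and populates:

    ``vim_matrix_`` : VimMatrix
        Source x target importances, normalised to sum one per target.
    ``alphas_`` : pd.Series
        Per-target decay rates actually used.

    Parameters
    ----------
    n_trees : int
        Ensemble size per target (default 1000).
    max_features : str or float
        Feature subsampling per split; default "sqrt" of the source count.
    alpha_mode : "from_data" or float
        Decay-rate handling, see :func:`estimate_alpha`.
    ensemble : "extra_trees" or "rf"
        Randomized-threshold trees (default) or classic random forests.
    importance : "impurity" or "permutation"
        Edge-weight statistic; impurity reduction is the family convention.
    random_state : int
        Seed for the per-target ensemble substreams.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        max_features: str | float = "sqrt",
        alpha_mode: str | float = "from_data",
        alpha_floor: float = ALPHA_FLOOR,
        ensemble: str = "extra_trees",
        importance: str = "impurity",
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.alpha_mode = alpha_mode
        self.alpha_floor = alpha_floor
        self.ensemble = ensemble
        self.importance = importance
        self.random_state = random_state

    def _make_ensemble(self, rs: int):
        kwargs = dict(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=rs,
        )
        if self.ensemble == "extra_trees":
            return ExtraTreesRegressor(bootstrap=False, **kwargs)
        if self.ensemble == "rf":
            return RandomForestRegressor(**kwargs)
        raise DesignError(f"unknown ensemble {self.ensemble!r}")

    def fit(
        self,
        source_trajs: Sequence[Trajectory],
        target_trajs: Sequence[Trajectory],
    ) -> "TimeSeriesGRN":
        _check_series_compatible(source_trajs, target_trajs)
        source_genes = list(source_trajs[0].gene_ids)
        target_genes = list(target_trajs[0].gene_ids)
        ratio = len(source_genes) / len(target_genes)
        if not (0.5 <= ratio <= 2.0):
            warnings.warn(
                f"unbalanced analysis: {len(source_genes)} source vs "
                f"{len(target_genes)} target genes (ratio {ratio:.2f}); "
                "a balanced amount of input and output genes is recommended",
                stacklevel=2,
            )

        # Canonical gene order (sorted ids) so results depend on gene
        # identity, never on input position.
        src_order = sorted(range(len(source_genes)), key=lambda i: source_genes[i])
        tgt_order = sorted(range(len(target_genes)), key=lambda j: target_genes[j])

        if isinstance(self.alpha_mode, pd.Series):
            missing = set(target_genes) - set(self.alpha_mode.index)
            if missing:
                raise DesignError(f"alpha missing for targets: {sorted(missing)}")
            if (self.alpha_mode.loc[target_genes] <= 0).any():
                raise DesignError("per-target alphas must be positive")
            alphas = self.alpha_mode.loc[target_genes].astype(float)
        else:
            alphas = pd.Series(
                {
                    g: estimate_alpha(
                        target_trajs, g, mode=self.alpha_mode, floor=self.alpha_floor
                    )
                    for g in target_genes
                }
            )

        # training rows: pooled consecutive-timepoint pairs over all series
        x_rows, y_rows = [], []
        for s_traj, t_traj in zip(source_trajs, target_trajs):
            times = np.asarray(s_traj.times, dtype=float)
            if len(times) < 2:
                continue
            sv = s_traj.values[src_order]
            tv = t_traj.values[tgt_order]
            for k in range(len(times) - 1):
                dt = times[k + 1] - times[k]
                x_rows.append(sv[:, k])
                y_rows.append((tv[:, k + 1] - tv[:, k]) / dt)
            # add alpha * x_j(t_k) per target below (needs per-target alpha)
        X = np.array(x_rows)
        dxdt = np.array(y_rows)  # rows x targets (in canonical target order)
        if X.shape[0] < 2:
            raise DesignError("fewer than 2 training rows; need longer series")

        # x_j(t_k) per row, canonical target order, for the decay term
        x_state = []
        for t_traj in target_trajs:
            tv = t_traj.values[tgt_order]
            for k in range(len(t_traj.times) - 1):
                x_state.append(tv[:, k])
        x_state = np.array(x_state)

        canonical_targets = [target_genes[j] for j in tgt_order]
        canonical_sources = [source_genes[i] for i in src_order]
        seeds = np.random.SeedSequence(self.random_state).spawn(len(canonical_targets))
        vim_canonical = np.zeros((len(canonical_sources), len(canonical_targets)))
        for jc, gene in enumerate(canonical_targets):
            y = dxdt[:, jc] + alphas[gene] * x_state[:, jc]
            rs = int(seeds[jc].generate_state(1)[0] % (2**31 - 1))
            est = self._make_ensemble(rs)
            est.fit(X, y)
            if self.importance == "impurity":
                imp = est.feature_importances_
            elif self.importance == "permutation":
                from sklearn.inspection import permutation_importance

                res = permutation_importance(
                    est, X, y, n_repeats=10, random_state=rs
                )
                imp = np.clip(res.importances_mean, 0.0, None)
            else:
                raise DesignError(f"unknown importance {self.importance!r}")
            total = imp.sum()
            vim_canonical[:, jc] = imp / total if total > 0 else 0.0

        canonical = pd.DataFrame(
            vim_canonical, index=canonical_sources, columns=canonical_targets
        )
        frame = canonical.loc[source_genes, target_genes]
        self.alphas_ = alphas.loc[target_genes]
        self.vim_matrix_ = VimMatrix(
            frame=frame,
            metadata={
                "n_trees": self.n_trees,
                "seed": self.random_state,
                "alpha_mode": (
                    self.alpha_mode
                    if isinstance(self.alpha_mode, (str, int, float))
                    else "per_target"
                ),
                "ensemble": self.ensemble,
                "importance": self.importance,
                "n_source": len(source_genes),
                "n_target": len(target_genes),
            },
        )
        return self


def infer_vim(
    source_trajs: Sequence[Trajectory],
    target_trajs: Sequence[Trajectory],
    alphas: str | float | pd.Series = "from_data",
    n_trees: int = 1000,
    seed: int = 0,
    **kwargs,
) -> VimMatrix:
    """Functional wrapper over :class:`TimeSeriesGRN`.

    ``alphas`` may be an alpha mode (see :func:`estimate_alpha`) or a
    precomputed per-target Series (must cover every target gene).
    """
    est = TimeSeriesGRN(
        n_trees=n_trees, alpha_mode=alphas, random_state=seed, **kwargs
    )
    est.fit(source_trajs, target_trajs)
    return est.vim_matrix_
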