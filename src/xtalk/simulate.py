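"""Synthetic two-tissue time-course study with a planted regulatory network.

The generator emulates a cross-sectional diet study: at each sacrifice
timepoint (default weeks 6, 12, 18, 24) an independent batch of animals
(default 6 chow, 15 HFD) contributes one liver and one aorta sample. Liver
"source" genes respond to the HFD with monotone log-scale shifts whose onset
and pace differ per gene, staggered by process category (lipid metabolism
first, inflammation mid-study, fibrosis late) — the temporal ordering that
diet-induced steatohepatitis studies report. Each aorta "target" gene
integrates a first-order decay model driven by its planted regulators:

    z_j(t_{k+1}) = z_j(t_k) + dt * ( -alpha_j z_j(t_k) + sum_i w_ij s_ij u_i(t_k) )

where u_i is the source's deviation from its chow baseline and z_j the
target's deviation from its own baseline; count means are exp(baseline +
deviation). This is exactly the decay-rate dynamical model the network
inference stage assumes, so edge recovery is a well-posed benchmark.
Per-animal counts are independent negative-binomial draws (variance
mu + phi mu^2) around the shared latent trajectory.

Ground truth (adjacency, signs, weights, decay rates, diet effects) is
returned alongside the data for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DesignError
from .io import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
    SampleSheet,
    write_gmt,
)

__all__ = ["SimulationTruth", "SimulatedStudy", "simulate_study", "score_recovery"]

_SOURCE_CATEGORY_WEIGHTS = {"lipid": 0.4, "inflammation": 0.3, "fibrosis": 0.3}
_TARGET_CATEGORY_WEIGHTS = {"inflammation": 0.5, "lipid": 0.3, "fibrosis": 0.2}
#: Category-specific (onset window, ramp-duration window) in weeks. The
#: windows track the reported staging of the disease processes: lipid
#: handling is fully deregulated by the first sacrifice (week 6),
#: inflammatory programs switch on between weeks 6 and 12, and fibrotic
#: programs between weeks 12 and 18 — switch-like transitions with
#: gene-specific onset and pace.
_CATEGORY_KINETICS = {
    "lipid": ((0.0, 3.0), (2.0, 5.0)),
    "inflammation": ((7.0, 11.0), (2.0, 5.0)),
    "fibrosis": ((13.0, 17.0), (2.0, 5.0)),
}
#: Probability that a gene of the category is up-regulated on HFD (cholesterol
#: biosynthesis regulators are predominantly down, inflammatory/fibrotic up).
_UP_PROBABILITY = {"lipid": 0.3, "inflammation": 0.8, "fibrosis": 0.8}


@dataclass
class SimulationTruth:
    """Planted ground truth of a simulated study."""

    source_genes: list[str]
    target_genes: list[str]
    adjacency: pd.DataFrame          # source x target in {0,1}
    effect_sign: pd.DataFrame        # source x target in {-1,0,+1}
    effect_weight: pd.DataFrame      # source x target >= 0
    decay_alpha: pd.Series           # per target, per-week decay rate > 0
    diet_effect: pd.Series           # per source, signed full-course log shift
    seed: int
    onset: pd.Series = field(default=None)      # per source, weeks
    duration: pd.Series = field(default=None)   # per source, weeks
    source_baseline: pd.Series = field(default=None)
    target_baseline: pd.Series = field(default=None)
    source_category: pd.Series = field(default=None)
    target_category: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        adj = self.adjacency.to_numpy()
        if not ((self.effect_sign.to_numpy() != 0) == (adj == 1)).all():
            raise DesignError("effect_sign must be nonzero exactly on edges")
        if not ((self.effect_weight.to_numpy() > 0) == (adj == 1)).all():
            raise DesignError("effect_weight must be positive exactly on edges")
        if not (self.decay_alpha > 0).all():
            raise DesignError("decay rates must be positive")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.adjacency.to_csv(outdir / "truth_adjacency.tsv", sep="\t")
        self.effect_sign.to_csv(outdir / "truth_sign.tsv", sep="\t")
        self.effect_weight.to_csv(outdir / "truth_weight.tsv", sep="\t")
        self.decay_alpha.rename("alpha").to_csv(outdir / "truth_alpha.tsv", sep="\t")
        self.diet_effect.rename("diet_effect").to_csv(
            outdir / "truth_diet_effect.tsv", sep="\t"
        )


@dataclass
class SimulatedStudy:
    liver: CountMatrix
    aorta: CountMatrix
    sheet: SampleSheet
    phenotype: PhenotypeTable
    truth: SimulationTruth
    #: latent log-scale trajectories, keyed (tissue, diet) -> genes x timepoints
    latent: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def gene_sets(self, n_decoy_per_set: int = 5) -> GeneSetCollection:
        """Gene sets matching the planted process categories.

        One liver set per source category and one aorta set per target
        category (each padded with a few background genes), plus one decoy
        background set per tissue. Planted genes carry expected directions:
        the sign of the diet effect (sources) or of the net late-study drive
        (targets).
        """
        truth = self.truth
        sets = []
        liver_bg = [g for g in self.liver.gene_ids if g not in truth.source_genes]
        aorta_bg = [g for g in self.aorta.gene_ids if g not in truth.target_genes]
        hfd_target = self.latent.get(("aorta", "HFD"))
        for cat in sorted(set(truth.source_category)):
            genes = [g for g in truth.source_genes if truth.source_category[g] == cat]
            decoys = liver_bg[: n_decoy_per_set]
            direction = {
                g: int(np.sign(truth.diet_effect[g])) for g in genes
                if truth.diet_effect[g] != 0
            }
            sets.append(
                GeneSet(
                    name=f"liver_{cat}",
                    category=cat,
                    genes=frozenset(genes + decoys),
                    expected_direction=direction,
                )
            )
        for cat in sorted(set(truth.target_category)):
            genes = [g for g in truth.target_genes if truth.target_category[g] == cat]
            decoys = aorta_bg[: n_decoy_per_set]
            direction = {}
            if hfd_target is not None:
                for g in genes:
                    dev = hfd_target.loc[g].iloc[-1] - truth.target_baseline[g]
                    if dev != 0:
                        direction[g] = int(np.sign(dev))
            sets.append(
                GeneSet(
                    name=f"aorta_{cat}",
                    category=cat,
                    genes=frozenset(genes + decoys),
                    expected_direction=direction,
                )
            )
        if len(liver_bg) > n_decoy_per_set:
            sets.append(
                GeneSet(
                    name="liver_background",
                    category="other",
                    genes=frozenset(liver_bg[n_decoy_per_set:]),
                )
            )
        if len(aorta_bg) > n_decoy_per_set:
            sets.append(
                GeneSet(
                    name="aorta_background",
                    category="other",
                    genes=frozenset(aorta_bg[n_decoy_per_set:]),
                )
            )
        return GeneSetCollection(tuple(sets))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.liver.write(outdir / "liver_counts.tsv")
        self.aorta.write(outdir / "aorta_counts.tsv")
        self.sheet.write(outdir / "sample_sheet.tsv")
        self.phenotype.write(outdir / "phenotype.tsv")
        write_gmt(self.gene_sets(), outdir / "gene_sets.gmt")
        self.truth.write(outdir)


def _assign_categories(rng, names: list[str], weights: dict[str, float]) -> pd.Series:
    cats = list(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    p /= p.sum()
    # deterministic proportional assignment with random shuffling
    n = len(names)
    base = (p * n).astype(int)
    while base.sum() < n:
        base[int(rng.integers(len(cats)))] += 1
    labels = np.repeat(cats, base)
    rng.shuffle(labels)
    return pd.Series(labels[:n], index=names)


def _source_deviation(
    t: float, effect: float, onset: float, duration: float
) -> float:
    """Signed log-scale deviation of a source gene at week t on HFD.

    A linear ramp from the gene's onset week to saturation after its ramp
    duration; monotone in t.
    """
    if t <= 0:
        return 0.0
    ramp = min(max((t - onset) / duration, 0.0), 1.0)
    return effect * ramp


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + dispersion * mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_study(
    n_source: int = 50,
    n_target: int = 20,
    n_background: int = 100,
    edges_per_target: int = 5,
    timepoints: tuple[int, ...] = (6, 12, 18, 24),
    n_chow: int = 6,
    n_hfd: int = 15,
    dispersion: float = 0.1,
    seed: int = 0,
    truth: SimulationTruth | None = None,
    shared_animal_sd: float = 0.0,
    saturating: bool = False,
) -> SimulatedStudy:
    """Simulate a two-tissue cross-sectional time-course study.

    Parameters
    ----------
    n_source, n_target : int
        Planted liver regulators and aorta targets.
    n_background : int
        Additional diet-independent genes per tissue.
    edges_per_target : int
        Regulators per target in the planted bipartite graph.
    timepoints : sequence of int
        Sacrifice weeks (at least 3).
    n_chow, n_hfd : int
        Animals per diet per timepoint (cross-sectional: fresh animals each
        timepoint); both tissues are sampled from the same animals.
    dispersion : float
        NB dispersion phi in var = mu + phi mu^2 (must be > 0).
    truth : SimulationTruth, optional
        Reuse an existing planted network (e.g. to simulate an independent
        follow-up study of the same biology); only noise and animals differ.
    shared_animal_sd : float
        Optional per-animal log-normal noise shared between the two tissues
        of an animal (0 disables it: the sacrifice design gives no
        within-animal liver-aorta coupling by default).
    saturating : bool
        Apply a tanh saturation to regulator deviations in the target
        dynamics — a deliberate model-mismatch scenario (off by default).
    """
    if edges_per_target > n_source:
        raise DesignError("edges_per_target cannot exceed n_source")
    if len(timepoints) < 3:
        raise DesignError("need at least 3 timepoints")
    if sorted(timepoints) != list(timepoints) or len(set(timepoints)) != len(timepoints):
        raise DesignError("timepoints must be strictly increasing")
    if n_chow < 2 or n_hfd < 2:
        raise DesignError("need at least 2 animals per diet per timepoint")
    if dispersion <= 0:
        raise DesignError("dispersion must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    source_genes = [f"L{i+1:03d}" for i in range(n_source)]
    target_genes = [f"A{j+1:03d}" for j in range(n_target)]
    liver_bg = [f"LB{i+1:03d}" for i in range(n_background)]
    aorta_bg = [f"AB{j+1:03d}" for j in range(n_background)]

    if truth is None:
        truth = _plant_truth(
            rng, source_genes, target_genes, edges_per_target, seed
        )
    else:
        if list(truth.source_genes) != source_genes or list(truth.target_genes) != target_genes:
            raise DesignError("reused truth does not match the requested gene panel")

    # --- latent log-scale trajectories ------------------------------------
    times = np.array(timepoints, dtype=float)
    grid = np.concatenate([[0.0], times])  # diet starts at week 0
    n_t = len(times)

    src_dev = {
        "chow": np.zeros((n_source, n_t)),
        "HFD": np.array(
            [
                [
                    _source_deviation(
                        t, truth.diet_effect[g], truth.onset[g], truth.duration[g]
                    )
                    for t in times
                ]
                for g in source_genes
            ]
        ),
    }

    W = truth.effect_weight.to_numpy() * truth.effect_sign.to_numpy()  # src x tgt
    alpha = truth.decay_alpha.to_numpy()
    tgt_dev = {}
    for diet in ("chow", "HFD"):
        z = np.zeros(n_target)
        dev = np.zeros((n_target, n_t))
        for k in range(len(grid) - 1):
            dt = grid[k + 1] - grid[k]
            t_now = grid[k]
            if t_now == 0.0:
                u = np.zeros(n_source)
            else:
                idx = int(np.where(times == t_now)[0][0])
                u = src_dev[diet][:, idx]
            if saturating:
                u = np.tanh(u)
            z = z + dt * (-alpha * z + W.T @ u)
            dev[:, k + 1 - 1] = z  # state at grid[k+1] == times[k]
        tgt_dev[diet] = dev

    latent: dict[tuple[str, str], pd.DataFrame] = {}
    b_src = truth.source_baseline.to_numpy()
    b_tgt = truth.target_baseline.to_numpy()
    bg_base_liver = rng.uniform(np.log(20.0), np.log(500.0), size=n_background)
    bg_base_aorta = rng.uniform(np.log(20.0), np.log(500.0), size=n_background)
    for diet in ("chow", "HFD"):
        liver_lat = np.vstack(
            [b_src[:, None] + src_dev[diet], np.tile(bg_base_liver[:, None], (1, n_t))]
        )
        aorta_lat = np.vstack(
            [b_tgt[:, None] + tgt_dev[diet], np.tile(bg_base_aorta[:, None], (1, n_t))]
        )
        latent[("liver", diet)] = pd.DataFrame(
            liver_lat, index=source_genes + liver_bg, columns=list(timepoints)
        )
        latent[("aorta", diet)] = pd.DataFrame(
            aorta_lat, index=target_genes + aorta_bg, columns=list(timepoints)
        )

    # --- animals, counts, sample sheet ------------------------------------
    sheet_rows = []
    liver_cols: dict[str, np.ndarray] = {}
    aorta_cols: dict[str, np.ndarray] = {}
    for ti, t in enumerate(timepoints):
        for diet, n_rep in (("chow", n_chow), ("HFD", n_hfd)):
            for r in range(n_rep):
                animal = f"m{t:02d}{'c' if diet == 'chow' else 'h'}{r+1:02d}"
                shift = rng.normal(0.0, shared_animal_sd) if shared_animal_sd > 0 else 0.0
                for tissue, cols in (("liver", liver_cols), ("aorta", aorta_cols)):
                    mu = np.exp(latent[(tissue, diet)].iloc[:, ti].to_numpy() + shift)
                    cols[f"{tissue}_{animal}"] = _nb_draw(rng, mu, dispersion)
                sheet_rows.append(
                    {"animal": animal, "tissue_pair": True, "diet": diet, "time": t}
                )

    sheet_records = []
    for row in sheet_rows:
        for tissue in ("liver", "aorta"):
            sheet_records.append(
                {
                    "sample_id": f"{tissue}_{row['animal']}",
                    "animal_id": row["animal"],
                    "tissue": tissue,
                    "diet": row["diet"],
                    "time_weeks": row["time"],
                }
            )
    sheet = SampleSheet(pd.DataFrame(sheet_records))
    liver = CountMatrix(
        pd.DataFrame(liver_cols, index=source_genes + liver_bg)
    )
    aorta = CountMatrix(
        pd.DataFrame(aorta_cols, index=target_genes + aorta_bg)
    )

    phenotype = _simulate_phenotypes(rng, sheet)

    return SimulatedStudy(
        liver=liver,
        aorta=aorta,
        sheet=sheet,
        phenotype=phenotype,
        truth=truth,
        latent=latent,
    )


def _plant_truth(
    rng, source_genes, target_genes, edges_per_target, seed
) -> SimulationTruth:
    n_source, n_target = len(source_genes), len(target_genes)
    source_category = _assign_categories(rng, source_genes, _SOURCE_CATEGORY_WEIGHTS)
    target_category = _assign_categories(rng, target_genes, _TARGET_CATEGORY_WEIGHTS)

    up_p = source_category.map(_UP_PROBABILITY).to_numpy(dtype=float)
    sign_src = np.where(rng.random(n_source) < up_p, 1.0, -1.0)
    magnitude = rng.uniform(2.0, 4.0, size=n_source)
    diet_effect = pd.Series(sign_src * magnitude, index=source_genes)
    on_lo = np.array([_CATEGORY_KINETICS[c][0][0] for c in source_category])
    on_hi = np.array([_CATEGORY_KINETICS[c][0][1] for c in source_category])
    du_lo = np.array([_CATEGORY_KINETICS[c][1][0] for c in source_category])
    du_hi = np.array([_CATEGORY_KINETICS[c][1][1] for c in source_category])
    onset = pd.Series(rng.uniform(on_lo, on_hi), index=source_genes)
    duration = pd.Series(rng.uniform(du_lo, du_hi), index=source_genes)

    # process-coherent wiring: a target's regulators come from its own
    # category's source pool (topped up from the remaining sources only when
    # the pool is too small)
    adjacency = np.zeros((n_source, n_target), dtype=int)
    sign = np.zeros((n_source, n_target), dtype=int)
    weight = np.zeros((n_source, n_target))
    pools = {
        cat: np.flatnonzero((source_category == cat).to_numpy())
        for cat in set(source_category)
    }
    for j, tcat in enumerate(target_category):
        pool = pools.get(tcat, np.arange(n_source))
        if len(pool) >= edges_per_target:
            regs = rng.choice(pool, size=edges_per_target, replace=False)
        else:
            rest = np.setdiff1d(np.arange(n_source), pool)
            extra = rng.choice(
                rest, size=edges_per_target - len(pool), replace=False
            )
            regs = np.concatenate([pool, extra])
        adjacency[regs, j] = 1
        sign[regs, j] = rng.choice([-1, 1], size=edges_per_target)
        weight[regs, j] = rng.uniform(0.05, 0.15, size=edges_per_target)

    return SimulationTruth(
        source_genes=list(source_genes),
        target_genes=list(target_genes),
        adjacency=pd.DataFrame(adjacency, index=source_genes, columns=target_genes),
        effect_sign=pd.DataFrame(sign, index=source_genes, columns=target_genes),
        effect_weight=pd.DataFrame(weight, index=source_genes, columns=target_genes),
        decay_alpha=pd.Series(
            rng.uniform(0.05, 0.15, size=n_target), index=target_genes
        ),
        diet_effect=diet_effect,
        seed=seed,
        onset=onset,
        duration=duration,
        source_baseline=pd.Series(
            rng.uniform(np.log(50.0), np.log(500.0), size=n_source), index=source_genes
        ),
        target_baseline=pd.Series(
            rng.uniform(np.log(50.0), np.log(500.0), size=n_target), index=target_genes
        ),
        source_category=source_category,
        target_category=target_category,
    )


# Group means (and SEMs) emulating the reported metabolic phenotype of the
# diet model: body weight g, glucose mM, insulin ng/mL, steatosis %,
# inflammation aggregates/mm2, fibrosis %. Interpolated linearly where only
# study-end values are reported.
_PHENO_MEANS = {
    "body_weight": {
        "chow": {6: 32.0, 12: 34.0, 18: 35.5, 24: 36.7},
        "HFD": {6: 38.0, 12: 43.0, 18: 48.0, 24: 51.8},
    },
    "glucose": {
        "chow": {6: 6.7, 12: 6.7, 18: 6.7, 24: 6.7},
        "HFD": {6: 6.9, 12: 6.9, 18: 6.9, 24: 6.9},
    },
    "insulin": {
        "chow": {6: 2.0, 12: 2.0, 18: 2.0, 24: 2.0},
        "HFD": {6: 6.0, 12: 10.0, 18: 15.0, 24: 20.7},
    },
    "steatosis": {
        "chow": {6: 0.0, 12: 0.2, 18: 1.8, 24: 0.3},
        "HFD": {6: 33.6, 12: 53.4, 18: 69.3, 24: 59.3},
    },
    "inflammation": {
        "chow": {6: 1.0, 12: 2.0, 18: 2.2, 24: 0.7},
        "HFD": {6: 6.1, 12: 5.4, 18: 10.6, 24: 12.1},
    },
    "fibrosis": {
        "chow": {6: 0.0, 12: 0.0, 18: 0.0, 24: 0.0},
        "HFD": {6: 0.0, 12: 0.0, 18: 2.5, 24: 5.0},
    },
}

_PHENO_CV = {
    "body_weight": 0.08,
    "glucose": 0.10,
    "insulin": 0.35,
    "steatosis": 0.18,
    "inflammation": 0.60,
    "fibrosis": 0.90,
}

# lesion_area = L0 + L2 * steatosis^2 + noise: lesions grow superlinearly
# with steatosis late in the study (quadratic lesion-steatosis relation).
_LESION_BASE = 20.0
_LESION_QUAD = 0.03
_LESION_NOISE_SD = 20.0


def _pheno_mean(var: str, diet: str, t: int) -> float:
    table = _PHENO_MEANS[var][diet]
    if t in table:
        return table[t]
    ts = sorted(table)
    t = min(max(t, ts[0]), ts[-1])
    return float(np.interp(t, ts, [table[k] for k in ts]))


def _simulate_phenotypes(rng, sheet: SampleSheet) -> PhenotypeTable:
    animals = (
        sheet.frame[["animal_id", "diet", "time_weeks"]]
        .drop_duplicates("animal_id")
        .reset_index(drop=True)
    )
    rows = []
    for rec in animals.itertuples():
        row = {"animal_id": rec.animal_id, "diet": rec.diet, "time_weeks": rec.time_weeks}
        for var, cv in _PHENO_CV.items():
            mean = _pheno_mean(var, rec.diet, rec.time_weeks)
            value = max(rng.normal(mean, cv * mean) if mean > 0 else 0.0, 0.0)
            if var in ("steatosis", "fibrosis"):
                value = min(value, 100.0)
            row[var] = value
        row["lesion_area"] = max(
            _LESION_BASE
            + _LESION_QUAD * row["steatosis"] ** 2
            + rng.normal(0.0, _LESION_NOISE_SD),
            0.0,
        )
        rows.append(row)
    return PhenotypeTable(pd.DataFrame(rows))


def score_recovery(vim, truth: SimulationTruth) -> dict[str, float]:
    """AUROC/AUPR of ranking all source-target pairs by VIM against truth.

    ``vim`` may be a VimMatrix or a source x target DataFrame; it must index
    the same genes as the truth. Ties are handled by mid-rank (the AUROC of a
    constant scoring is 0.5).
    """
    frame = getattr(vim, "frame", vim)
    if set(frame.index) != set(truth.source_genes) or set(frame.columns) != set(
        truth.target_genes
    ):
        raise DesignError("VIM and truth index different gene panels")
    scores = frame.loc[truth.source_genes, truth.target_genes].to_numpy().ravel()
    labels = truth.adjacency.to_numpy().ravel()
    if labels.sum() == 0:
        raise DesignError("truth has no positive edges")
    if labels.min() == labels.max():
        raise DesignError("truth has no negative edges")
    if np.ptp(scores) == 0:
        return {"auroc": 0.5, "aupr": float(labels.mean())}
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }
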