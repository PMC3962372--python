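"""Nested leave-one-out experiment and between-combination statistics.

For one subject (20 trials) and one segment combination the experiment runs a
double LOOCV: the outer loop holds one trial out as the test set and fits the
feature ICA on the remaining 19; the inner loop holds one of those 19 out as
the early-stopping validation trial and trains the network on the other 18.
Every trained network classifies the projected test trial, so a subject
yields 20 x 19 = 380 scored trial instances per combination. The held-out
test trial never enters ICA fitting or network training/validation.

Component counts follow the two-stage design: the full-body dataset uses the
count picked by the ranking stage's variance criterion, while reduced segment
subsets keep all 3-per-segment dimensions (information reduction already
happened by dropping segments).

Between-combination comparison is the usual protocol-level analysis: a paired t-test of
each reduced combination's detection times against the full-body baseline
(paired over subject x perturbation type), and per combination a two-way
main-effects ANOVA of detection time on belt direction (5 levels) and
perturbed side (2 levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from . import detect, ica, nn
from .kinematics import assemble_dataset
from .segments import MIDLINE, PARTNER, SEGMENTS, subset_channels
from .synth import PerturbationType, TrialWindow

#: the standard combinations: full body (ALL), feet (F), hands (H), feet+hands (F-H)
NAMED_COMBINATIONS: dict[str, list[str]] = {
    "ALL": list(SEGMENTS),
    "F": ["LF", "RF"],
    "H": ["LH", "RH"],
    "F-H": ["LH", "RH", "LF", "RF"],
}


def _check_bilateral(name: str, segs: list[str]) -> list[str]:
    chosen = set(segs)
    for s in chosen:
        if s not in SEGMENTS:
            raise ValueError(f"combination {name!r}: unknown segment {s}")
        if s not in MIDLINE and PARTNER[s] not in chosen:
            raise ValueError(
                f"combination {name!r} is not bilateral: {s} without {PARTNER[s]}")
    return [s for s in SEGMENTS if s in chosen]


@dataclass
class ExperimentConfig:
    """Everything one subject's experiment depends on, keyed by a master seed."""

    combinations: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in NAMED_COMBINATIONS.items()})
    var_threshold: float = 0.95
    train: nn.TrainConfig = field(default_factory=nn.TrainConfig)
    run_length: int = detect.RUN_LENGTH_DEFAULT
    threshold: float = detect.THRESHOLD_DEFAULT
    ica_restarts: int = 5
    ica_max_iter: int = 500
    ica_tol: float = 1e-4
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.combinations = {name: _check_bilateral(name, segs)
                             for name, segs in self.combinations.items()}

    def ica1_seed(self) -> int:
        return (self.master_seed ^ 0x1CA1) & 0x7FFFFFFF

    def ica2_seed(self, outer: int) -> int:
        return (self.master_seed ^ ((outer + 1) << 10)) & 0x7FFFFFFF

    def nn_seed(self, outer: int, inner: int) -> int:
        return (self.master_seed ^ (outer * 32 + inner + 1) ^ 0x2E7) & 0x7FFFFFFF


@dataclass
class FoldPlan:
    """Outer/inner leave-one-out index structure over n trials."""

    n_trials: int

    def outer_folds(self) -> list[tuple[int, list[int]]]:
        """(test index, training indices) pairs; every trial tests once."""
        all_ids = list(range(self.n_trials))
        return [(i, [j for j in all_ids if j != i]) for i in all_ids]

    def inner_folds(self, train_ids: list[int]) -> list[tuple[int, list[int]]]:
        """(validation index, fit indices) pairs within one outer fold."""
        return [(j, [k for k in train_ids if k != j]) for j in train_ids]


# ---------------------------------------------------------------------------
# ranking stage (ICA1)
# ---------------------------------------------------------------------------

def run_ranking(trials: list[TrialWindow],
                cfg: ExperimentConfig) -> tuple[ica.SegmentRanking, ica.ICAModel]:
    """Fit ICA1 on the full dataset M and rank segments by TSW.

    Also determines N, the retained-component count reused by the full-body
    feature stage. Note the ranking deliberately sees all 20 trials — it runs
    before the cross-validation loops, as a data-driven sensor-placement
    choice, not as part of the classifier under test.
    """
    M, _, _ = assemble_dataset(trials)
    n = ica.select_n_components(M, cfg.var_threshold)
    model = ica.fit_ica(M, n, seed=cfg.ica1_seed(), restarts=cfg.ica_restarts,
                        max_iter=cfg.ica_max_iter, tol=cfg.ica_tol)
    return ica.compute_tsw(model), model


# ---------------------------------------------------------------------------
# double LOOCV
# ---------------------------------------------------------------------------

def _combo_n_components(segs: list[str], n_all: int | None) -> int:
    """N for ICA2: the variance-selected count for the full body, the full
    3-per-segment dimension for reduced subsets."""
    if set(segs) == set(SEGMENTS):
        if n_all is None:
            raise ValueError("full-body combination needs the ICA1 component count")
        return n_all
    return 3 * len(segs)


def run_outer_fold(trials: list[TrialWindow], test_idx: int,
                   combo_segments: list[str], cfg: ExperimentConfig,
                   n_components: int,
                   collect_models: bool = False):
    """One outer fold: ICA2 on the 19 training trials, 19 inner networks,
    each classifying the projected held-out trial.

    Returns the fold's outcomes and, when requested, the trained models
    (used e.g. to assert that the test trial cannot influence training).
    """
    ch = subset_channels(combo_segments)
    train_ids = [t for t in range(len(trials)) if t != test_idx]
    tr_mat = np.concatenate([trials[t].accel[ch] for t in train_ids], axis=1)
    ica2 = ica.fit_ica(tr_mat, n_components, seed=cfg.ica2_seed(test_idx),
                       restarts=cfg.ica_restarts, max_iter=cfg.ica_max_iter,
                       tol=cfg.ica_tol)
    proj = {t: ica.project(ica2, trials[t].accel[ch]) for t in train_ids}
    s_test = ica.project(ica2, trials[test_idx].accel[ch])
    test = trials[test_idx]

    outcomes, models = [], []
    for val_idx in train_ids:
        fit_ids = [t for t in train_ids if t != val_idx]
        s_fit = np.concatenate([proj[t] for t in fit_ids], axis=1)
        y_fit = np.concatenate([trials[t].label for t in fit_ids])
        tcfg = nn.TrainConfig(**{**cfg.train.__dict__,
                                 "seed": cfg.nn_seed(test_idx, val_idx)})
        model, _ = nn.train_nn(s_fit, y_fit, proj[val_idx],
                               trials[val_idx].label, tcfg)
        raw = nn.nn_forward(model, s_test)
        outcomes.append(detect.classify_trial(
            raw, test.fs, test.onset_index, ptype=test.ptype.code,
            threshold=cfg.threshold, run_length=cfg.run_length))
        if collect_models:
            models.append(model)
    return (outcomes, models) if collect_models else (outcomes, None)


def run_subject(trials: list[TrialWindow], combo_segments: list[str],
                cfg: ExperimentConfig, n_components: int | None = None,
                combination_name: str | None = None) -> detect.PerformanceReport:
    """Full double LOOCV for one subject and one segment combination.

    Requires the protocol's 20-trial set; aggregates all 20 x 19 classified
    test-trial instances into one performance report. Deterministic given
    ``cfg.master_seed``.
    """
    if len(trials) != 20:
        raise ValueError(f"expected 20 trials (2 sessions x 10 types), got {len(trials)}")
    combo_segments = _check_bilateral(combination_name or "combo", list(combo_segments))
    n_comp = _combo_n_components(combo_segments, n_components)
    outcomes = []
    for test_idx, _ in FoldPlan(len(trials)).outer_folds():
        fold_out, _ = run_outer_fold(trials, test_idx, combo_segments, cfg, n_comp)
        outcomes.extend(fold_out)
    return detect.aggregate(outcomes, combination=combination_name)


def run_experiment(trials: list[TrialWindow], cfg: ExperimentConfig
                   ) -> tuple[dict[str, detect.PerformanceReport], ica.SegmentRanking]:
    """Ranking plus one report per configured combination for one subject."""
    ranking, _ = run_ranking(trials, cfg)
    reports = {}
    for name, segs in cfg.combinations.items():
        n_all = ranking.n_retained if set(segs) == set(SEGMENTS) else None
        reports[name] = run_subject(trials, segs, cfg, n_components=n_all,
                                    combination_name=name)
    return reports, ranking


# ---------------------------------------------------------------------------
# between-combination statistics
# ---------------------------------------------------------------------------

def mdt_frame(reports_by_subject: dict[str, dict[str, detect.PerformanceReport]]
              ) -> pd.DataFrame:
    """Long-format MDT table: one row per subject x perturbation type x
    combination, the unit of the between-combination statistics."""
    rows = []
    for subject, combos in reports_by_subject.items():
        for combo, report in combos.items():
            for code, sub in report.by_type.items():
                rows.append({"subject": subject, "ptype": code,
                             "combination": combo, "mdt": sub.mdt_mean})
    return pd.DataFrame(rows)


def _anova_direction_side(df: pd.DataFrame) -> dict:
    """Two-way main-effects ANOVA of MDT on direction (5) and side (2)."""
    data = df.copy()
    pts = [PerturbationType(c) for c in data["ptype"]]
    data["direction"] = [p.direction for p in pts]
    data["side"] = [p.side for p in pts]
    fit = ols("mdt ~ C(direction) + C(side)", data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return {
        "direction_F": float(table.loc["C(direction)", "F"]),
        "direction_p": float(table.loc["C(direction)", "PR(>F)"]),
        "direction_df": int(table.loc["C(direction)", "df"]),
        "side_F": float(table.loc["C(side)", "F"]),
        "side_p": float(table.loc["C(side)", "PR(>F)"]),
        "side_df": int(table.loc["C(side)", "df"]),
        "resid_df": int(table.loc["Residual", "df"]),
    }


def compare_combinations(mdt: pd.DataFrame, baseline: str = "ALL",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Combination comparison table: MDT summary, direction/side ANOVA, and a
    paired t-test of each reduced combination against the baseline.

    ``mdt`` is the long table from :func:`mdt_frame`. Pairing is by subject x
    perturbation type; a missing cell (e.g. a combination with no true
    positive for some subject and type) is an error naming the cells. The
    degenerate all-zero-difference t-test is reported as t = 0, p = 1.
    """
    required = {"subject", "ptype", "combination", "mdt"}
    if not required.issubset(mdt.columns):
        raise ValueError(f"mdt table must have columns {sorted(required)}")
    combos = list(dict.fromkeys(mdt["combination"]))
    if baseline not in combos:
        raise ValueError(f"baseline {baseline!r} not present")
    cells = mdt.pivot_table(index=["subject", "ptype"], columns="combination",
                            values="mdt", aggfunc="first")
    missing = [(idx, c) for c in combos for idx in cells.index[cells[c].isna()]]
    if missing:
        raise ValueError(f"missing MDT cells: {missing}")

    rows = []
    for combo in combos:
        sub = mdt[mdt["combination"] == combo]
        row = {"combination": combo,
               "mdt_mean_ms": 1000.0 * sub["mdt"].mean(),
               "mdt_sd_ms": 1000.0 * sub["mdt"].std(ddof=1)}
        row.update(_anova_direction_side(sub))
        if combo == baseline:
            row.update({"t_vs_baseline": np.nan, "t_df": np.nan,
                        "p_vs_baseline": np.nan, "significant": False})
        else:
            diff = cells[combo] - cells[baseline]
            if np.allclose(diff, 0.0):
                t_stat, p_val = 0.0, 1.0
            else:
                t_stat, p_val = stats.ttest_rel(cells[combo], cells[baseline])
            row.update({"t_vs_baseline": float(t_stat),
                        "t_df": len(diff) - 1,
                        "p_vs_baseline": float(p_val),
                        "significant": bool(p_val < alpha)})
        rows.append(row)
    return pd.DataFrame(rows)
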