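"""End-to-end study pipeline: simulate cohorts, fit severity models,
evaluate discrimination, and report tables mirroring a clinical analysis.

``run_pipeline`` produces, per run directory:

* ``demographics.csv`` — per-group eye/subject counts and covariate
  prevalences (cohort-characteristics table);
* ``odds_ratios.csv`` — complete multinomial mixed-model ORs on reporting
  scales (per 0.001 VSD, per 0.01 VDI);
* ``evaluation.csv`` — AUCs with CIs for the nested model family per
  contrast, paired AUC-contrast p-values against the covariate-only model,
  10-fold cross-validated AUC, and the external-cohort transport row;
* ``cutoffs.json`` — ROC-optimal VSD/VDI cutoffs on one best eye per
  subject, with correct classification rates;
* ``log.txt`` / ``config.yaml`` — provenance (seed, package versions,
  binarization defaults) and the exact configuration for re-runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._rng import subseed
from . import metrics as metrics_mod
from .model import (
    MixedMultinomialLogit,
    constrained_comparison,
    hosmer_lemeshow,
)
from .roc import (
    compare_auc,
    external_validate,
    kfold_cv_auc,
    optimal_cutoff,
    roc_auc,
    sens_spec_at,
)
from .simulate import CohortConfig, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "power_check"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Serializable configuration for one reproducible pipeline run."""

    seed: int = 0
    k_folds: int = 10
    full_model: Sequence[str] = ("vsd", "vdi", "male", "htn", "hld")
    covariate_model: Sequence[str] = ("male", "htn", "hld")
    or_deltas: dict = field(default_factory=lambda: {"vsd": 0.001, "vdi": 0.01})
    cohort1_kwargs: dict = field(default_factory=dict)
    cohort2_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not set(self.covariate_model) <= set(self.full_model):
            raise ValueError("covariate_model must be nested in full_model")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["full_model"] = list(self.full_model)
        d["covariate_model"] = list(self.covariate_model)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def power_check(group_means, group_sds, group_ns, alpha: float = 0.05) -> dict:
    """Two-sample normal-approximation power for each listed comparison.

    Arguments are dicts keyed by comparison name, each value a (a, b) pair
    of group means / SDs / sample sizes.  Power for detecting the observed
    mean difference at two-sided level alpha:

        z = |m_a - m_b| / sqrt(s_a^2/n_a + s_b^2/n_b)
        power = Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2})
    """
    z_a = stats.norm.ppf(1 - alpha / 2)
    out = {}
    for name in group_means:
        (m1, m2), (s1, s2), (n1, n2) = (
            group_means[name],
            group_sds[name],
            group_ns[name],
        )
        if s1 <= 0 or s2 <= 0:
            raise ValueError(f"nonpositive SD in comparison {name!r}")
        if n1 < 2 or n2 < 2:
            raise ValueError(f"need n >= 2 per group in comparison {name!r}")
        se = math.sqrt(s1 * s1 / n1 + s2 * s2 / n2)
        z = abs(m1 - m2) / se
        out[name] = float(stats.norm.cdf(z - z_a) + stats.norm.cdf(-z - z_a))
    return out


def _demographics(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (cohort, group), sub in df.groupby(["cohort", "dr_class"], sort=False):
        subj = sub.drop_duplicates("subject_id")
        rows.append(
            dict(
                cohort=cohort,
                dr_class=group,
                n_eyes=len(sub),
                n_subjects=sub["subject_id"].nunique(),
                female_pct=100 * (subj["sex"] == "F").mean(),
                htn_pct=100 * subj["htn"].mean(),
                hld_pct=100 * subj["hld"].mean(),
                age_mean=subj["age"].mean(),
                age_sd=subj["age"].std(),
                vsd_mean=sub["vsd"].mean(),
                vsd_sd=sub["vsd"].std(),
                vdi_mean=sub["vdi"].mean(),
                vdi_sd=sub["vdi"].std(),
            )
        )
    return pd.DataFrame(rows)


def _contrast_builder(contrast):
    def build(df):
        if contrast == "any_vs_control":
            sub = df
            y = (df["dr_class"] != "control").astype(int)
        else:
            sub = df[df["dr_class"].isin(["mild", "referable"])]
            y = (sub["dr_class"] == "referable").astype(int)
        return sub, y

    return build


def _stage(log, name):
    log.append(f"[{time.strftime('%H:%M:%S')}] stage: {name}")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> fit -> evaluate and write the report bundle.

    Returns a dict with the in-memory results (tables and fit objects).
    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure are left in place.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []
    results: dict = {}
    stage = "setup"
    try:
        _stage(log, "simulate cohorts")
        stage = "simulate"
        c1 = generate_cohort(
            CohortConfig.cohort1(seed=subseed(config.seed, "cohort1"),
                                 **config.cohort1_kwargs)
        )
        c2 = generate_cohort(
            CohortConfig.cohort2(seed=subseed(config.seed, "cohort2"),
                                 **config.cohort2_kwargs)
        )
        for frame in (c1, c2):
            frame["male"] = (frame["sex"] == "M").astype(int)
        results["cohort1"], results["cohort2"] = c1, c2

        _stage(log, "demographics table")
        stage = "demographics"
        demo = _demographics(pd.concat([c1, c2], ignore_index=True))
        demo.to_csv(out / "demographics.csv", index=False)
        results["demographics"] = demo

        _stage(log, "multinomial severity model")
        stage = "multinomial-model"
        mn = MixedMultinomialLogit.from_dataframe(
            c1, "dr_class", list(config.full_model)
        ).fit()
        or_table = mn.odds_ratios(config.or_deltas)
        or_table.to_csv(out / "odds_ratios.csv", index=False)
        results["multinomial"] = mn
        results["odds_ratios"] = or_table
        log.append(f"  subject-intercept SD: {mn.vc_sd.get('subject', 0):.3f}; "
                   f"converged={mn.converged}")

        _stage(log, "constrained contrasts + ROC evaluation")
        stage = "evaluation"
        eval_rows = []
        fits = {}
        for contrast in ("any_vs_control", "referable_vs_mild"):
            build = _contrast_builder(contrast)
            sub, y = build(c1)
            model_sets = {
                "model1": list(config.covariate_model),
                "model1+vsd": list(config.covariate_model) + ["vsd"],
                "model1+vdi": list(config.covariate_model) + ["vdi"],
                "model1+vsd+vdi": list(config.full_model),
            }
            scores = {}
            for mname, cols in model_sets.items():
                fit = constrained_comparison(c1, contrast, cols)
                fits[(contrast, mname)] = fit
                scores[mname] = fit.predict_linear(sub)
            base = scores["model1"]
            for mname, lp in scores.items():
                rr = roc_auc(lp, y)
                contrast_p = (
                    np.nan
                    if mname == "model1"
                    else compare_auc(lp, base, y).p_value
                )
                sens, spec = sens_spec_at(lp, y)
                row = dict(
                    cohort=1,
                    contrast=contrast,
                    model=mname,
                    auc=rr.auc,
                    auc_lo=rr.auc_ci[0],
                    auc_hi=rr.auc_ci[1],
                    p_vs_model1=contrast_p,
                    sensitivity=sens,
                    specificity=spec,
                    cv_auc=np.nan,
                )
                if mname == "model1+vsd+vdi":
                    cv = kfold_cv_auc(
                        c1,
                        build,
                        model_sets[mname],
                        k=config.k_folds,
                        seed=subseed(config.seed, "cv", contrast),
                    )
                    row["cv_auc"] = cv.mean_auc
                    hl = hosmer_lemeshow(fits[(contrast, mname)].fittedvalues,
                                         fits[(contrast, mname)].model.endog)
                    log.append(
                        f"  {contrast}: CV AUC {cv.mean_auc:.3f}; "
                        f"Hosmer-Lemeshow p = {hl['p_value']:.3f}"
                    )
                eval_rows.append(row)

        _stage(log, "external validation on cohort 2")
        stage = "external-validation"
        build2 = _contrast_builder("referable_vs_mild")
        sub2, y2 = build2(c2)
        lp2 = {}
        for mname in ("model1", "model1+vsd", "model1+vdi", "model1+vsd+vdi"):
            fit = fits[("referable_vs_mild", mname)]
            rr = external_validate(fit, sub2, y2)
            lp2[mname] = fit.predict_linear(sub2)
            contrast_p = (
                np.nan
                if mname == "model1"
                else compare_auc(lp2[mname], lp2["model1"], y2).p_value
            )
            sens, spec = sens_spec_at(lp2[mname], y2)
            eval_rows.append(
                dict(
                    cohort=2,
                    contrast="referable_vs_mild",
                    model=mname,
                    auc=rr.auc,
                    auc_lo=rr.auc_ci[0],
                    auc_hi=rr.auc_ci[1],
                    p_vs_model1=contrast_p,
                    sensitivity=sens,
                    specificity=spec,
                    cv_auc=np.nan,
                )
            )
        evaluation = pd.DataFrame(eval_rows)
        evaluation.to_csv(out / "evaluation.csv", index=False)
        results["evaluation"] = evaluation

        _stage(log, "optimal cutoffs (one best eye per subject, both cohorts)")
        stage = "cutoffs"
        combined = pd.concat([c1, c2], ignore_index=True)
        best = metrics_mod.select_best_eye(combined)
        cutoffs = {}
        for contrast in ("any_vs_control", "referable_vs_mild"):
            sub, y = _contrast_builder(contrast)(best)
            if y.nunique() < 2:
                continue
            for metric, direction in (("vsd", "below_positive"), ("vdi", "above_positive")):
                c = optimal_cutoff(sub[metric].to_numpy(), y.to_numpy(), direction)
                nd = 3 if metric == "vsd" else 2
                cutoffs[f"{metric}_{contrast}"] = {
                    "threshold": round(c.threshold, nd),
                    "correct_classification_rate": c.correct_classification_rate,
                    "direction": direction,
                    "n_subjects": c.n,
                }
        (out / "cutoffs.json").write_text(json.dumps(cutoffs, indent=1))
        results["cutoffs"] = cutoffs

        _stage(log, "post-hoc power")
        stage = "power"
        g1 = demo[demo.cohort == 1].set_index("dr_class")
        comparisons = {
            "any_vs_control_vsd": ("control", "mild", "vsd"),
        }
        means, sds, ns = {}, {}, {}
        for a, b, metric in (
            ("control", "mild", "vsd"),
            ("control", "mild", "vdi"),
            ("mild", "referable", "vsd"),
            ("mild", "referable", "vdi"),
        ):
            name = f"{a}_vs_{b}_{metric}"
            means[name] = (g1.loc[a, f"{metric}_mean"], g1.loc[b, f"{metric}_mean"])
            sds[name] = (g1.loc[a, f"{metric}_sd"], g1.loc[b, f"{metric}_sd"])
            ns[name] = (g1.loc[a, "n_eyes"], g1.loc[b, "n_eyes"])
        power = power_check(means, sds, ns)
        results["power"] = power
        log.append("  power: " + ", ".join(f"{k}={v:.3f}" for k, v in power.items()))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        (out / "log.txt").write_text("\n".join(log + [f"FAILED in stage {stage}: {exc}"]))
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _stage(log, "provenance")
    import capnet

    log.append(
        f"  seed={config.seed}  capnet={capnet.__version__}  "
        f"numpy={np.__version__}  python={sys.version.split()[0]}  "
        f"binarization={metrics_mod.DEFAULT_BINARIZATION}"
    )
    (out / "log.txt").write_text("\n".join(log))
    config.to_yaml(out / "config.yaml")
    return results
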