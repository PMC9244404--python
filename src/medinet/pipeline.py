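"""End-to-end pipeline: simulate/load -> score -> network -> compare -> model.

Writes all tabular outputs plus a manifest recording the configuration, the
master seed and a content hash of every file, so identical runs are
byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import compare as compare_mod
from . import models as models_mod
from . import network as network_mod
from .cohort import CohortConfig
from .scoring import score_cohort

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (a participant CSV) or ``simulate`` must be
    set; ``cohort_config`` applies only when simulating.
    """

    output_dir: str | Path = "medinet_run"
    input_path: str | Path | None = None
    simulate: bool = False
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    n_perm: int = 1000
    n_reshuffles: int = 1000
    edge_rule: str = "perm"
    master_seed: int = 0

    def validate(self) -> None:
        if bool(self.input_path) == bool(self.simulate):
            raise ValueError("exactly one of input_path / simulate must be specified")
        if self.n_perm < 100 or self.n_reshuffles < 100:
            raise ValueError("n_perm and n_reshuffles must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def _model_fit_dict(fit: models_mod.ModelFit) -> dict:
    return {
        "kind": fit.model_kind,
        "n": fit.n_used,
        "coefficients": fit.coefficients,
        "std_betas": fit.std_betas,
        "p_values": fit.p_values,
        "r_squared": fit.r_squared,
        "r_squared_by_block": fit.r_squared_by_block,
        "statistic": fit.statistic,
        "converged": fit.converged,
        "notes": fit.notes,
    }


def _fit_outcome_models(scored: pd.DataFrame, hubs_ms: tuple[str, ...],
                        alpha: float) -> dict:
    """Hub -> outcome models on the MS group, mirroring the analysis plan:
    sensitivity analysis, collinearity screen, per-hub bivariate logistic
    models, hierarchical OLS for EDSS and FSS."""
    from .scoring import ITEMS

    ms = scored[scored["group"] == "MS"]
    classes = models_mod.classify_outcomes(ms["edss"].to_numpy(), ms["fss"].to_numpy())
    report: dict = {"fss_median": classes.fss_median, "models": {}}

    sens = models_mod.min_detectable_beta(len(ms), alpha=alpha, power=0.90)
    report["sensitivity"] = {
        "n": sens.n, "alpha": sens.alpha, "power": sens.power,
        "min_beta": sens.min_beta, "assumptions": sens.assumptions,
    }

    hub_items = [h for h in hubs_ms if h in ITEMS]
    if len(hub_items) >= 2:
        screen = models_mod.collinearity_screen(ms[hub_items], alpha=alpha)
        report["collinearity"] = {
            "pairs": screen.pairs.to_dict(orient="records"),
            "joint_model_allowed": screen.joint_model_allowed,
        }
    else:
        report["collinearity"] = {"pairs": [], "joint_model_allowed": True}

    for outcome_name, outcome in (
        ("disability", classes.disability_class),
        ("fatigue", classes.fatigue_class),
    ):
        for hub in hub_items:
            key = f"bivariate_logistic:{outcome_name}~{hub}"
            try:
                fit = models_mod.bivariate_logistic(outcome, ms[hub].to_numpy(dtype=float))
                report["models"][key] = _model_fit_dict(fit)
            except (ValueError, models_mod.SeparationError) as exc:
                report["models"][key] = {"kind": "bivariate_logistic", "error": str(exc)}

    report["models"]["hierarchical:edss~lifestyle+negative_foods"] = _model_fit_dict(
        models_mod.hierarchical_ols(ms["edss"].to_numpy(), [
            ("lifestyle", ms[["pack_years", "ipaq_met"]]),
            ("negative_foods", ms[["negative_score"]]),
        ])
    )
    report["models"]["hierarchical:fss~lifestyle"] = _model_fit_dict(
        models_mod.hierarchical_ols(ms["fss"].to_numpy(), [
            ("lifestyle", ms[["pack_years", "ipaq_met"]]),
        ])
    )
    return report


def _group_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Descriptive MS-vs-HC comparisons of demographics and scores."""
    ms = scored[scored["group"] == "MS"]
    hc = scored[scored["group"] == "HC"]
    rows = []
    for col in ("age", "bmi", "waist_cm", "hip_cm", "whr", "medi_total",
                "ipaq_met", "pack_years"):
        fit = models_mod.group_compare(ms[col].to_numpy(), hc[col].to_numpy(), kind="t_test")
        rows.append({
            "variable": col, "test": "t",
            "ms_mean": ms[col].mean(), "hc_mean": hc[col].mean(),
            "statistic": fit.statistic, "p_value": fit.p_values["t"],
        })
    table = np.array([
        [(ms["sex"] == "F").sum(), (ms["sex"] == "M").sum()],
        [(hc["sex"] == "F").sum(), (hc["sex"] == "M").sum()],
    ])
    fit = models_mod.group_compare(table, kind="chi_square")
    rows.append({
        "variable": "sex(F/M)", "test": "chi2",
        "ms_mean": (ms["sex"] == "F").mean(), "hc_mean": (hc["sex"] == "F").mean(),
        "statistic": fit.statistic, "p_value": fit.p_values["chi2"],
    })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all outputs under ``output_dir``.

    Returns the manifest.  On any failure, partially written outputs are
    removed before the exception propagates.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, sep: str = "\t", index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep=sep, index=index, float_format=_FLOAT_FMT)
        written.append(path)

    try:
        if config.simulate:
            cc = config.cohort_config
            if cc.seed != config.master_seed:
                from dataclasses import replace
                cc = replace(cc, seed=config.master_seed)
            table = cohort_mod.generate_cohort(cc)
        else:
            table = cohort_mod.read_cohort_csv(config.input_path)
            cohort_mod.validate_cohort(table)

        scored = score_cohort(table)
        path = out / "scored.csv"
        scored.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

        networks = {}
        hubs_json = {}
        for group in ("MS", "HC"):
            sub = scored[scored["group"] == group]
            encoded = network_mod.encode_cohort(sub)
            net = network_mod.build_network(
                encoded, edge_rule=config.edge_rule, alpha=config.alpha,
                n_perm=config.n_perm, seed=config.master_seed,
            )
            networks[group] = net
            save_df(net.mi.to_frame(), f"mi_{group.lower()}.tsv", index=True)
            save_df(net.edge_table(), f"edges_{group.lower()}.tsv")
            hubset = network_mod.identify_hubs(net)
            hubs_json[group] = {
                "degrees": hubset.degrees,
                "threshold": hubset.threshold,
                "hubs": list(hubset.hubs),
            }
        path = out / "hubs.json"
        _write_json(path, hubs_json)
        written.append(path)

        diff = compare_mod.compare_groups(
            networks["MS"].mi, networks["HC"].mi,
            n_reshuffles=config.n_reshuffles, seed=config.master_seed,
            alpha=config.alpha,
        )
        save_df(diff.to_frame(), "comparison.tsv")
        path = out / "comparison_verdict.json"
        _write_json(path, {
            "no_difference": diff.no_difference,
            "n_significant_cells": int(diff.significant.sum() // 2),
            "z_critical": diff.z_crit,
            "n_reshuffles": diff.n_reshuffles,
        })
        written.append(path)

        models_report = _fit_outcome_models(scored, tuple(hubs_json["MS"]["hubs"]),
                                            config.alpha)
        path = out / "models.json"
        _write_json(path, models_report)
        written.append(path)

        save_df(_group_table(scored), "group_comparisons.tsv")

        manifest = {
            "config": {
                "alpha": config.alpha,
                "n_perm": config.n_perm,
                "n_reshuffles": config.n_reshuffles,
                "edge_rule": config.edge_rule,
                "master_seed": config.master_seed,
                "simulate": config.simulate,
                "input_path": str(config.input_path) if config.input_path else None,
                "n_ms": int((scored["group"] == "MS").sum()),
                "n_hc": int((scored["group"] == "HC").sum()),
            },
            "outputs": {p.name: _sha256(p) for p in written},
            "n_model_fits": len(models_report["models"]),
        }
        path = out / "manifest.json"
        _write_json(path, manifest)
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
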