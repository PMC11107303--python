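"""End-to-end orchestration: config -> comparison sets -> report bundle.

One root seed feeds named substreams per stage (rates, adjusted fits,
bootstrap, pooling, PRO) so any stage can be re-run in isolation and two runs
with the same inputs are byte-identical.  Display conventions follow the
source tables: percentages to 1 dp, ORs to 2 dp, equivalence probabilities to
1 dp percent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjusted, meta, pro, rates, synthetic, trial_model

DEFAULT_INSTRUMENTS = {
    "metformin": "promis",
    "ivermectin": "promis",
    "pegylated interferon lambda": "promis",
    "fluvoxamine+budesonide": "promis",
    "fluvoxamine": "promis",
    "famotidine": "eq5d",
    "spirulina": "eq5d",
}


def derive_seed(root_seed: int, label: str) -> int:
    """Stable per-stage substream seed below 2^31."""
    digest = hashlib.sha256(f"{root_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: str | Path
    seed: int = 0
    records_csv: str | Path | None = None     # else: synthesize from trial_config
    trial_config: synthetic.TrialConfig | None = None
    mcmc_chains: int = 4
    mcmc_total_iters: int = 20_000
    bootstrap_B: int = 1000
    equiv_bounds: tuple[float, float] = (0.8, 1.2)
    instruments: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENTS)
    )
    value_set_path: str | Path | None = None  # else: synthetic additive set
    run_pro: bool = True
    mice_m: int = 15
    mice_cycles: int = 10
    mice_donors: int = 5
    tobit_iters: int = 8000

    def __post_init__(self) -> None:
        lo, hi = self.equiv_bounds
        if not (0.0 < lo < 1.0 < hi):
            raise ValueError("equivalence bounds must satisfy 0 < lo < 1 < hi")


@dataclass
class ReportBundle:
    """In-memory results plus the paths written."""

    comparisons: list[trial_model.ComparisonSet]
    table1: pd.DataFrame
    meta_fixed: meta.MetaResult
    meta_random: meta.MetaResult
    pooled: meta.PooledEquivalence
    table2: pd.DataFrame | None
    paths: dict[str, Path]


def _fmt_pct(x: float) -> float:
    return rates.round_half_up(100.0 * x, 1)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if cfg.records_csv is not None:
        records = trial_model.read_records(cfg.records_csv)
        trial_cfg = cfg.trial_config or synthetic.default_config()
    else:
        trial_cfg = cfg.trial_config or synthetic.default_config()
        records = synthetic.generate_trial(trial_cfg, derive_seed(cfg.seed, "synth"))
    index = {r.id: r for r in records}

    comparisons = [
        trial_model.build_comparison(spec, records) for spec in trial_cfg.treatments
    ]
    paths["comparisons"] = out / "comparisons.tsv"
    trial_model.write_comparison_manifest(comparisons, paths["comparisons"])

    # --- Table-1-style unadjusted rates + adjusted ORs ---------------------
    rows = []
    estimates = []
    for k, cs in enumerate(comparisons):
        table = trial_model.extract_two_by_two(cs, index)
        p_m, p_u = rates.group_posteriors(table)
        fit = adjusted.fit_bayes_logistic(
            cs, index, chains=cfg.mcmc_chains, total_iters=cfg.mcmc_total_iters,
            seed=derive_seed(cfg.seed, f"logistic:{cs.treatment.name}"), warn=False,
        )
        aor = adjusted.adjusted_or(fit, equiv_bounds=cfg.equiv_bounds)
        g = fit.group_draws()
        estimates.append(
            meta.EffectEstimate(
                label=cs.treatment.name,
                log_or=float(np.median(g)),
                se=float(g.std(ddof=1)),
            )
        )
        for arm, post, n, events, aor_ in (
            ("matched", p_m, table.n_a, table.events_a, None),
            ("nonmatched combined", p_u, table.n_b, table.events_b, aor),
        ):
            lo, hi = rates.credible_interval_pct(post)
            rows.append({
                "treatment": cs.treatment.name, "arm": arm, "n": n,
                "events": events, "rate_pct": post.mean_pct,
                "cri_lo_pct": lo, "cri_hi_pct": hi,
                "aor": round(aor_.or_point, 2) if aor_ else "",
                "aor_lo": round(aor_.cri_95[0], 2) if aor_ else "",
                "aor_hi": round(aor_.cri_95[1], 2) if aor_ else "",
                "prob_equiv_pct": _fmt_pct(aor_.prob_equiv) if aor_ else "",
            })
    table1 = pd.DataFrame(rows)
    paths["table1"] = out / "table1_rates_aor.tsv"
    table1.to_csv(paths["table1"], sep="\t", index=False)

    # --- pooled meta-analysis ---------------------------------------------
    sigma = meta.bootstrap_covariance(
        comparisons, records, B=cfg.bootstrap_B,
        seed=derive_seed(cfg.seed, "bootstrap"),
    )
    decoupled = meta.decouple(estimates, sigma)
    fe = meta.fixed_effect_meta(decoupled)
    re = meta.random_effect_meta(decoupled)
    pooled = meta.bayes_meta(
        decoupled, seed=derive_seed(cfg.seed, "bayes-meta"), bounds=cfg.equiv_bounds,
        chains=cfg.mcmc_chains, total_iters=cfg.mcmc_total_iters,
    )

    forest = pd.DataFrame([
        {
            "label": e.label,
            "or": round(np.exp(e.log_or), 2),
            "lo": round(np.exp(e.log_or - meta.Z_95 * e.se), 2),
            "hi": round(np.exp(e.log_or + meta.Z_95 * e.se), 2),
            "weight_pct": _fmt_pct(
                (1 / e.se**2) / sum(1 / d.se**2 for d in decoupled)
            ),
        }
        for e in decoupled
    ] + [{
        "label": "pooled (fixed effect)",
        "or": round(fe.pooled_or, 2),
        "lo": round(fe.or_ci_95[0], 2),
        "hi": round(fe.or_ci_95[1], 2),
        "weight_pct": 100.0,
    }])
    paths["forest"] = out / "forest.tsv"
    forest.to_csv(paths["forest"], sep="\t", index=False)

    grid = np.linspace(
        max(1e-6, float(np.exp(pooled.mu_draws.min()))),
        float(np.exp(pooled.mu_draws.max())), 241,
    )
    from scipy import stats as _st
    kde = _st.gaussian_kde(np.exp(pooled.mu_draws))
    density = pd.DataFrame({"or_grid": grid, "density": kde(grid)})
    density["equiv_lo"] = cfg.equiv_bounds[0]
    density["equiv_hi"] = cfg.equiv_bounds[1]
    paths["density"] = out / "pooled_posterior_density.tsv"
    density.to_csv(paths["density"], sep="\t", index=False, float_format="%.6f")

    # --- patient-reported outcomes ----------------------------------------
    table2 = None
    if cfg.run_pro:
        value_set = (
            pro.ValueSet.load(cfg.value_set_path)
            if cfg.value_set_path
            else pro.synthetic_value_set()
        )
        pro_rows = []
        for cs in comparisons:
            instrument = cfg.instruments.get(cs.treatment.name, "promis")
            pooled_effect = pro.analyze_pro_comparison(
                cs, index, instrument, value_set,
                m=cfg.mice_m, cycles=cfg.mice_cycles, donors=cfg.mice_donors,
                seed=derive_seed(cfg.seed, f"pro:{cs.treatment.name}"),
                tobit_chains=cfg.mcmc_chains, tobit_iters=cfg.tobit_iters,
            )
            nd = 2 if instrument == "eq5d" else 2
            pro_rows.append({
                "treatment": cs.treatment.name,
                "instrument": instrument,
                "mean_difference": round(pooled_effect.estimate, nd),
                "lo": round(pooled_effect.ci_95[0], nd),
                "hi": round(pooled_effect.ci_95[1], nd),
                "interval_type": "CrI" if instrument == "eq5d" else "CI",
            })
        table2 = pd.DataFrame(pro_rows)
        paths["table2"] = out / "table2_pro.tsv"
        table2.to_csv(paths["table2"], sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "n_records": len(records),
        "equiv_bounds": list(cfg.equiv_bounds),
        "mcmc": {"chains": cfg.mcmc_chains, "total_iters": cfg.mcmc_total_iters},
        "bootstrap_B": cfg.bootstrap_B,
        "pooled_or": round(pooled.or_point, 2),
        "pooled_cri": [round(v, 2) for v in pooled.cri_95],
        "prob_equiv_pct": _fmt_pct(pooled.prob_equiv),
        "I2": round(fe.I2, 1),
    }
    paths["manifest"] = out / "run_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")

    return ReportBundle(
        comparisons=comparisons, table1=table1, meta_fixed=fe, meta_random=re,
        pooled=pooled, table2=table2, paths=paths,
    )


def meta_from_printed(table: pd.DataFrame) -> meta.MetaResult:
    """Meta-analysis straight from a printed table of (label, or, lo, hi).

    Converts each printed 95% interval to a log-OR/SE and runs the
    DerSimonian-Laird path; requires no patient-level data.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows")
    estimates = []
    for i, row in table.reset_index(drop=True).iterrows():
        try:
            estimates.append(
                meta.logor_from_ci(
                    float(row["or"]), float(row["lo"]), float(row["hi"]),
                    label=str(row.get("label", i)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed row {i}: {exc}") from exc
    return meta.random_effect_meta(estimates)
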