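"""End-to-end study runner: score -> associate -> survival -> report.

A single YAML config drives both simulated and real-input runs; the
``simulation`` and ``inputs`` blocks are mutually exclusive. All
machine-readable artifacts (TSV/JSON) are written with a manifest recording
the software version, a config hash and input checksums, so every number in
the rendered report can be recomputed from the bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import io as pio
from . import simulate as sim
from . import survival as surv
from .errors import ConfigError
from .grs import GRSResult, HIGH_CUT, LOW_CUT, compute_grs
from .phenotypes import PhenotypeRecord

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("low", "average", "elevated")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (simulated or file inputs)."""

    out_dir: Path
    simulation: Optional[sim.SimulationConfig] = None
    panel_path: Optional[Path] = None
    genotypes_path: Optional[Path] = None  # .vcf or .tsv by extension
    phenotypes_path: Optional[Path] = None
    low_cut: float = LOW_CUT
    high_cut: float = HIGH_CUT
    seed: int = 0
    model_terms: tuple[str, ...] = ("age", "male", "family_history", "bmi", "grs")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        has_sim = "simulation" in raw
        has_inputs = "inputs" in raw
        if has_sim == has_inputs:
            raise ConfigError(
                "config must contain exactly one of 'simulation' or 'inputs'"
            )
        kwargs: dict[str, Any] = {
            "out_dir": Path(raw.get("out_dir", "polygrs_run")),
            "seed": int(raw.get("seed", 0)),
            "low_cut": float(raw.get("low_cut", LOW_CUT)),
            "high_cut": float(raw.get("high_cut", HIGH_CUT)),
        }
        if "model_terms" in raw:
            kwargs["model_terms"] = tuple(raw["model_terms"])
        if has_sim:
            s = raw["simulation"] or {}
            spec_kwargs = s.pop("panel_spec", {})
            cov = s.pop("covariate_effects", {})
            kwargs["simulation"] = sim.SimulationConfig(
                panel_spec=sim.PanelSpec(**spec_kwargs),
                covariate_effects=sim.CovariateEffects(**cov),
                **s,
            )
        else:
            inp = raw["inputs"] or {}
            for key in ("panel", "genotypes", "phenotypes"):
                if key not in inp:
                    raise ConfigError(f"inputs block missing {key!r}")
            kwargs["panel_path"] = Path(inp["panel"])
            kwargs["genotypes_path"] = Path(inp["genotypes"])
            kwargs["phenotypes_path"] = Path(inp["phenotypes"])
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """Everything the rendered report is built from."""

    scores: list[GRSResult]
    phenotypes: list[PhenotypeRecord]
    table1: pd.DataFrame
    detection: assoc.TrendResult
    grs_means: assoc.MeanComparison
    km_curves: dict[str, pd.DataFrame]
    logrank: Optional[surv.LogrankResult]
    mean_ages: Optional[surv.GroupAges]
    table2: pd.DataFrame
    manifest: dict[str, Any] = field(default_factory=dict)


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        simcfg = dataclasses.replace(config.simulation, seed=config.seed)
        bundle = sim.generate_study(simcfg, out_dir=config.out_dir / "inputs")
        return bundle.panel, bundle.genotypes, bundle.phenotypes
    panel = pio.read_panel(config.panel_path)
    gpath = Path(config.genotypes_path)
    if gpath.suffix in (".vcf", ".gz", ".bcf"):
        genotypes = pio.read_genotypes_vcf(gpath, panel)
    else:
        genotypes = pio.read_genotypes_tsv(gpath, panel)
    phenotypes = pio.read_phenotypes(config.phenotypes_path)
    return panel, genotypes, phenotypes


def build_table1(
    scores: Sequence[GRSResult], phenotypes: Sequence[PhenotypeRecord],
    model_terms: Sequence[str] = ("age", "male", "family_history", "bmi", "grs"),
) -> pd.DataFrame:
    """Univariable and multivariable association of predictors with outcome.

    Univariable odds ratios come from single-term logistic fits (for the
    binary terms these equal the 2x2 cross-product OR); the multivariable
    column is a joint fit of all terms. GRS enters continuously.
    """
    grs_by_id = {s.subject_id: s.grs for s in scores}
    ph = [p for p in phenotypes if p.subject_id in grs_by_id]
    df = pd.DataFrame(
        {
            "age": [p.age_at_colonoscopy for p in ph],
            "male": [1.0 if p.sex == "male" else 0.0 for p in ph],
            "family_history": [1.0 if p.family_history else 0.0 for p in ph],
            "bmi": [np.nan if p.bmi is None else p.bmi for p in ph],
            "grs": [grs_by_id[p.subject_id] for p in ph],
        }
    )
    y = np.array([1.0 if p.outcome else 0.0 for p in ph])
    terms = [t for t in model_terms if t in df.columns]
    keep = ~df[terms].isna().any(axis=1)
    if (~keep).any():
        logger.warning("%d subject(s) dropped for missing covariates", int((~keep).sum()))
    df, y = df.loc[keep, terms], y[keep.to_numpy()]
    multi = assoc.fit_logistic(y, df)
    rows = []
    for t in terms:
        uni = assoc.fit_logistic(y, df[[t]])
        u, m = uni.term(t), multi.term(t)
        rows.append(
            {
                "term": t,
                "uni_or": u["odds_ratio"], "uni_ci_low": u["ci_low"],
                "uni_ci_high": u["ci_high"], "uni_p": u["p"],
                "multi_or": m["odds_ratio"], "multi_ci_low": m["ci_low"],
                "multi_ci_high": m["ci_high"], "multi_p": m["p"],
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["n_obs"] = multi.n_obs
    return out


def build_bundle(
    scores: Sequence[GRSResult],
    phenotypes: Sequence[PhenotypeRecord],
    model_terms: Sequence[str] = ("age", "male", "family_history", "bmi", "grs"),
) -> ReportBundle:
    """Run the full statistical battery on an already-scored cohort."""
    scored_ids = {s.subject_id for s in scores}
    phenotypes = [p for p in phenotypes if p.subject_id in scored_ids]
    table1 = build_table1(scores, phenotypes, model_terms)

    cat = {s.subject_id: s.category for s in scores}
    pos, tot = [], []
    present = [c for c in CATEGORY_ORDER if any(cat[p.subject_id] == c for p in phenotypes)]
    for c in present:
        members = [p for p in phenotypes if cat[p.subject_id] == c]
        pos.append(sum(p.outcome for p in members))
        tot.append(len(members))
    detection = assoc.trend_across_categories(pos, tot, categories=present)

    outcome_of = {p.subject_id: p.outcome for p in phenotypes}
    grs_means = assoc.compare_grs_means(
        {
            "positive": [s.grs for s in scores if outcome_of.get(s.subject_id)],
            "negative": [s.grs for s in scores if not outcome_of.get(s.subject_id)],
        }
    )

    records = surv.build_survival_records(scores, phenotypes)
    km = surv.km_estimate(records)
    logrank = (
        surv.logrank_test(records) if len({r.group for r in records}) >= 2 else None
    )
    ages = surv.mean_age_by_group(records) if records else None

    table2 = assoc.subgroup_associations(scores, phenotypes)
    return ReportBundle(
        scores=list(scores), phenotypes=phenotypes, table1=table1,
        detection=detection, grs_means=grs_means, km_curves=km, logrank=logrank,
        mean_ages=ages, table2=table2,
    )


def run_study(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline and write the machine-readable bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, genotypes, phenotypes = _load_inputs(config)
    logger.info("cohort: %d subjects, %d panel SNPs", genotypes.n_subjects, len(panel))

    scores = compute_grs(
        genotypes, panel, low_cut=config.low_cut, high_cut=config.high_cut
    )
    pio.write_scores(scores, out / "scores.tsv")

    bundle = build_bundle(scores, phenotypes, config.model_terms)
    table1, detection = bundle.table1, bundle.detection
    grs_means, km = bundle.grs_means, bundle.km_curves
    logrank, ages, table2 = bundle.logrank, bundle.mean_ages, bundle.table2

    # write machine-readable bundle
    table1.to_csv(out / "table1.tsv", sep="\t")
    table2.to_csv(out / "table2.tsv", sep="\t")
    pd.DataFrame(
        {
            "category": detection.categories,
            "positives": detection.positives,
            "totals": detection.totals,
            "rate": detection.rates,
        }
    ).to_csv(out / "detection_rates.tsv", sep="\t", index=False)
    for g, df in km.items():
        df.to_csv(out / f"km_{g}.tsv", sep="\t", index=False)

    stats = {
        "n_subjects": len(scores),
        "overall_detection_rate": float(sum(detection.positives) / sum(detection.totals)),
        "p_trend": detection.p_trend,
        "trend_z": detection.statistic,
        "grs_means": {
            g.label: {"n": g.n, "mean": g.mean, "ci": [g.ci_low, g.ci_high]}
            for g in grs_means.groups
        },
        "grs_t_p": grs_means.p_value,
        "logrank": None
        if logrank is None
        else {"chi2": logrank.statistic, "df": logrank.df, "p": logrank.p_value},
        "mean_age_by_group": None
        if ages is None
        else {"means": ages.means, "p": ages.p_value},
    }
    (out / "summary.json").write_text(json.dumps(stats, indent=2) + "\n")

    manifest = {
        "polygrs_version": _version(),
        "seed": config.seed,
        "cutpoints": [config.low_cut, config.high_cut],
        "config_hash": _config_hash(config),
        "inputs": _input_checksums(config, out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    bundle.manifest = manifest
    return bundle


def _version() -> str:
    from . import __version__

    return __version__


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _input_checksums(config: RunConfig, out: Path) -> dict[str, str]:
    paths = []
    if config.simulation is not None:
        inputs = out / "inputs"
        paths = sorted(inputs.glob("*")) if inputs.exists() else []
    else:
        paths = [config.panel_path, config.genotypes_path, config.phenotypes_path]
    return {
        str(p.name): hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        for p in paths
        if p and Path(p).exists()
    }


# ---------------------------------------------------------------- report ----


def _pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def render_report(bundle: ReportBundle, out_dir: Path) -> Path:
    """Write a human-readable markdown summary plus figures.

    Numbers are shown at display precision (ORs to 2 decimals, rates to one
    decimal percent); full precision lives in the TSV/JSON bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Screening cohort GRS report", ""]
    n = len(bundle.scores)
    overall = sum(bundle.detection.positives) / sum(bundle.detection.totals)
    lines += [
        f"Subjects scored: {n}",
        f"Overall adenoma detection rate: {_pct(overall)}",
        "",
        "## Predictor associations (univariable / multivariable)",
        "",
        "| term | OR (95% CI) | p | adj. OR (95% CI) | adj. p |",
        "|---|---|---|---|---|",
    ]
    for t, r in bundle.table1.iterrows():
        lines.append(
            f"| {t} | {r.uni_or:.2f} ({r.uni_ci_low:.2f}-{r.uni_ci_high:.2f}) "
            f"| {_fmt_p(r.uni_p)} | {r.multi_or:.2f} "
            f"({r.multi_ci_low:.2f}-{r.multi_ci_high:.2f}) | {_fmt_p(r.multi_p)} |"
        )
    lines += ["", "## Detection rate by GRS category", ""]
    for cat, p_, t_ in zip(
        bundle.detection.categories, bundle.detection.positives, bundle.detection.totals
    ):
        lines.append(f"- {cat}: {p_}/{t_} = {_pct(p_ / t_)}")
    lines.append(f"- p-trend = {_fmt_p(bundle.detection.p_trend)}")
    gm = {g.label: g for g in bundle.grs_means.groups}
    lines += [
        "",
        "## Mean GRS by outcome",
        "",
    ] + [
        f"- {label}: {g.mean:.2f} ({g.ci_low:.2f}-{g.ci_high:.2f}), n={g.n}"
        for label, g in gm.items()
    ] + [f"- Welch t-test p = {_fmt_p(bundle.grs_means.p_value)}"]
    if bundle.logrank is not None:
        lines += [
            "",
            "## Age at first adenoma diagnosis (Kaplan-Meier)",
            "",
            f"- log-rank chi-square = {bundle.logrank.statistic:.2f} "
            f"(df={bundle.logrank.df}), p = {_fmt_p(bundle.logrank.p_value)}",
        ]
        if bundle.mean_ages is not None and bundle.mean_ages.p_value is not None:
            means = ", ".join(
                f"{g}: {m:.1f} y" for g, m in bundle.mean_ages.means.items()
            )
            lines.append(
                f"- mean age at colonoscopy by group: {means} "
                f"(F-test p = {_fmt_p(bundle.mean_ages.p_value)})"
            )
    lines += ["", "## GRS by polyp subtype (vs no-polyp reference)", ""]
    lines += [
        "| subtype | n | mean GRS (95% CI) | OR (95% CI) | p |",
        "|---|---|---|---|---|",
    ]
    for name, r in bundle.table2.iterrows():
        flag = " *" if r.wide_ci_warning else ""
        lines.append(
            f"| {name}{flag} | {int(r.n)} | {r.grs_mean:.2f} "
            f"({r.grs_ci_low:.2f}-{r.grs_ci_high:.2f}) | {r.odds_ratio:.2f} "
            f"({r.ci_low:.2f}-{r.ci_high:.2f}) | {_fmt_p(r.p_value)} |"
        )
    if bundle.table2["wide_ci_warning"].any():
        lines.append("")
        lines.append("`*` fewer than 10 members; interval unstable.")

    _plot_figures(bundle, out)
    lines += [
        "",
        "Figures: `detection_rates.png` (rate by category), `km_curves.png` "
        "(diagnosis-free probability vs age).",
        "",
    ]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.2g}"


def _plot_figures(bundle: ReportBundle, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    cats = list(bundle.detection.categories)
    rates = [100 * r for r in bundle.detection.rates]
    ax.bar(cats, rates, color=["#4c72b0", "#dd8452", "#c44e52"][: len(cats)])
    for i, (r, p_, t_) in enumerate(
        zip(rates, bundle.detection.positives, bundle.detection.totals)
    ):
        ax.text(i, r + 0.5, f"{r:.1f}%\n({p_}/{t_})", ha="center", fontsize=8)
    missing = [c for c in CATEGORY_ORDER if c not in cats]
    if missing:
        ax.set_title(f"(empty: {', '.join(missing)})", fontsize=8)
    ax.set_ylabel("adenoma detection rate (%)")
    ax.set_xlabel("GRS risk category")
    fig.tight_layout()
    fig.savefig(out / "detection_rates.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for g, df in bundle.km_curves.items():
        ax.step(df["age"], df["survival"], where="post", label=g)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("adenoma-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="GRS category", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "km_curves.png", dpi=150)
    plt.close(fig)
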