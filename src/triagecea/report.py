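"""Run configuration, report tables and the full analysis pipeline.

``run_analysis`` drives the whole method on one cohort: per-strategy
summaries (counts, NNT, costs), pairwise incremental comparisons
against the reference strategy with analytic intervals, the paired
bootstrap with CEAC, and cost/biopsy distribution figures.  Outputs are
CSV (full precision plus rounded display columns), a markdown report,
the serialized config (provenance) and a log echoing seed and stages.

Display formatting is isolated here: whole-EUR rounding is half away
from zero, and ``--locale eu`` renders dotted thousands ("116.058").
No quantity is recomputed in the formatter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cohort import Cohort, UnitCostTable, read_cohort
from .costs import AllocationParadigm, round_eur
from .incremental import (
    DEFAULT_WTP_GRID,
    IcerStatus,
    PairwiseComparison,
    compare_all,
)
from .strategies import StrategySummary, builtin_strategies, summarize_strategy
from .synthetic import fixture_cohort
from .uncertainty import (
    BootstrapResult,
    UncertaintySpec,
    analytic_intervals,
    bootstrap_pairwise,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "format_eur", "strategy_summary_frame", "pairwise_frame"]


def format_eur(value: float, locale: str = "plain", *, unicode_minus: bool = False) -> str:
    """Whole-EUR display string; ``eu`` locale uses dotted thousands.

    >>> format_eur(116058, "eu")
    '116.058'
    """
    n = round_eur(float(value))
    if locale == "eu":
        s = f"{abs(n):,}".replace(",", ".")
        s = ("-" + s) if n < 0 else s
    elif locale == "plain":
        s = str(n)
    else:
        raise ValueError(f"unknown locale {locale!r}")
    if unicode_minus:
        s = s.replace("-", "−")
    return s


def strategy_summary_frame(
    summaries: Sequence[StrategySummary], locale: str = "plain"
) -> pd.DataFrame:
    """Per-strategy report table: raw values plus display columns."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "strategy": s.name,
                "label": s.label,
                "biopsies": s.biopsies,
                "cspca_detected": s.cspca_detected,
                "nnt": s.nnt,
                "nnt_display": "" if s.nnt is None else f"{s.nnt:.1f}",
                "biopsies_avoided": s.biopsies_avoided,
                "cspca_missed": s.cspca_missed,
                "total_cost_eur": s.total_cost_eur,
                "total_cost_display": format_eur(s.total_cost_eur, locale),
                "cost_per_cspca_eur": s.cost_per_cspca,
                "cost_per_cspca_display": ""
                if s.cost_per_cspca is None
                else format_eur(s.cost_per_cspca, locale),
            }
        )
    return pd.DataFrame(rows)


def pairwise_frame(
    comparisons: Sequence[PairwiseComparison],
    intervals: Optional[dict] = None,
    locale: str = "plain",
) -> pd.DataFrame:
    """Incremental comparison table (one row per candidate strategy)."""
    rows = []
    for c in comparisons:
        row = {
            "candidate": c.candidate,
            "reference": c.reference,
            "delta_e": c.delta_e,
            "delta_c_eur": c.delta_c,
            "delta_c_exact_eur": c.delta_c_exact,
            "icer_status": c.icer.status.value,
            "icer_eur": None if c.icer.value is None else c.icer.value,
            "icer_display": c.icer.display(),
        }
        for w, v in c.inb_per_patient.items():
            row[f"inb_per_patient_wtp{int(w)}"] = v
            row[f"inb_display_wtp{int(w)}"] = format_eur(v, locale)
        if intervals and c.candidate in intervals:
            iv = intervals[c.candidate]
            fe = iv.get("icer_fieller")
            if fe is not None:
                row["icer_fieller_lower"] = fe.lower
                row["icer_fieller_upper"] = fe.upper
            for w, est in iv["inb_delta"].items():
                row[f"inb_delta_lower_wtp{int(w)}"] = est.lower
                row[f"inb_delta_upper_wtp{int(w)}"] = est.upper
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Fully-validated configuration of one analysis run.

    Serialized into the output directory so a run can be reproduced
    byte-identically (same seed, same outputs).
    """

    cohort_path: Optional[str] = None  # None -> use the reference fixture
    unit_costs: dict = field(default_factory=lambda: UnitCostTable().to_dict())
    paradigm: str = "stepwise"
    reference: str = "mpmri"
    wtp_grid: tuple = DEFAULT_WTP_GRID
    cost_cv: float = 0.175
    cov_ce: float = 0.0
    cov_sign: int = +1
    bootstrap_B: int = 2000
    seed: int = 20260302
    out_dir: str = "triagecea_out"
    locale: str = "plain"
    psa_multiplier: int = 1
    make_figures: bool = True

    def __post_init__(self) -> None:
        AllocationParadigm.coerce(self.paradigm)
        UnitCostTable(**self.unit_costs)
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0 (0 disables the bootstrap)")
        if self.locale not in ("plain", "eu"):
            raise ValueError("locale must be 'plain' or 'eu'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if "wtp_grid" in data:
            data["wtp_grid"] = tuple(data["wtp_grid"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_path is None:
        logger.info("stage: cohort — using the built-in reference fixture")
        return fixture_cohort()
    return read_cohort(config.cohort_path)


def _figures(summaries, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [s.label for s in summaries]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(labels, [s.biopsies for s in summaries], color="#4878b0")
    ax.set_ylabel("fusion biopsies")
    ax.set_title("Biopsies per triage strategy")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out / "biopsies_per_strategy.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(labels, [s.total_cost_eur for s in summaries], color="#b05348")
    ax.set_ylabel("total cost (EUR)")
    ax.set_title("Cost distribution per triage strategy")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out / "cost_per_strategy.png", dpi=150)
    plt.close(fig)


def _markdown_report(
    config: RunConfig,
    cohort: Cohort,
    summary_df: pd.DataFrame,
    pairwise_df: pd.DataFrame,
    boots: dict[str, BootstrapResult],
) -> str:
    lines = [
        "# Triage strategy cost-effectiveness report",
        "",
        f"- cohort: n={cohort.n}, csPCa={cohort.n_cspca} "
        f"(prevalence {cohort.n_cspca / cohort.n:.3f})",
        f"- paradigm: {config.paradigm}; reference: {config.reference}; "
        f"WTP grid: {list(config.wtp_grid)}; seed: {config.seed}",
        "",
        "## Strategy summary",
        "",
        summary_df.drop(columns=[c for c in summary_df.columns if c.endswith("_display")])
        .to_markdown(index=False),
        "",
        f"## Pairwise vs {config.reference}",
        "",
        pairwise_df[
            [c for c in pairwise_df.columns
             if not c.startswith("inb_display") and "lower" not in c and "upper" not in c]
        ].to_markdown(index=False),
    ]
    if boots:
        lines += ["", "## Bootstrap CEAC (probability candidate is cost-effective)", ""]
        for name, b in boots.items():
            ceac = ", ".join(f"WTP {int(w)}: {v:.3f}" for w, v in b.ceac.items())
            lines.append(f"- {name} vs {b.reference} (B={b.B}, seed={b.seed}): {ceac}")
    lines.append("")
    return "\n".join(lines)


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the output paths and in-memory results.  Any
    stage failure propagates with the stage named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("triagecea")
    root.addHandler(fh)
    try:
        logger.info("run config: %s", config.to_json())
        cohort = _load_cohort(config)
        costs = UnitCostTable(**config.unit_costs)
        strategies = builtin_strategies()
        logger.info("stage: evaluate — %d strategies, paradigm=%s", len(strategies), config.paradigm)
        summaries = [
            summarize_strategy(
                cohort, s, costs, config.paradigm, psa_multiplier=config.psa_multiplier
            )
            for s in strategies
        ]
        summary_df = strategy_summary_frame(summaries, config.locale)
        summary_df.to_csv(out / "strategy_summary.csv", index=False)

        logger.info("stage: compare — reference=%s", config.reference)
        comparisons = compare_all(
            cohort, strategies, config.reference, costs, config.paradigm,
            config.wtp_grid, psa_multiplier=config.psa_multiplier,
        )
        spec = UncertaintySpec(
            cost_cv=config.cost_cv, cov_ce=config.cov_ce, cov_sign=config.cov_sign
        )
        prevalence = cohort.n_cspca / cohort.n
        intervals = {c.candidate: analytic_intervals(c, spec, prevalence) for c in comparisons}
        pair_df = pairwise_frame(comparisons, intervals, config.locale)
        pair_df.to_csv(out / "pairwise.csv", index=False)

        boots: dict[str, BootstrapResult] = {}
        if config.bootstrap_B > 0:
            logger.info("stage: bootstrap — B=%d seed=%d", config.bootstrap_B, config.seed)
            ref = next(s for s in strategies if s.name == config.reference)
            ceac_rows = []
            for s in strategies:
                if s.name == config.reference:
                    continue
                b = bootstrap_pairwise(
                    cohort, s, ref, costs, config.paradigm, config.wtp_grid,
                    B=config.bootstrap_B, seed=config.seed,
                    psa_multiplier=config.psa_multiplier,
                )
                boots[s.name] = b
                for w in config.wtp_grid:
                    ceac_rows.append(
                        {
                            "candidate": s.name,
                            "reference": config.reference,
                            "wtp": w,
                            "ceac": b.ceac[w],
                            "inb_lower": b.inb_ci[w].lower,
                            "inb_upper": b.inb_ci[w].upper,
                            "prop_zero_delta_e": b.prop_zero_delta_e,
                        }
                    )
            pd.DataFrame(ceac_rows).to_csv(out / "ceac.csv", index=False)

        if config.make_figures:
            logger.info("stage: figures")
            _figures(summaries, out)

        (out / "run_config.json").write_text(config.to_json() + "\n")
        report = _markdown_report(config, cohort, summary_df, pair_df, boots)
        (out / "report.md").write_text(report)
        logger.info("stage: done — outputs in %s", out)
        return {
            "out_dir": out,
            "cohort": cohort,
            "summaries": summaries,
            "summary_frame": summary_df,
            "comparisons": comparisons,
            "intervals": intervals,
            "pairwise_frame": pair_df,
            "bootstraps": boots,
        }
    finally:
        root.removeHandler(fh)
        fh.close()
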