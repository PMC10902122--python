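"""Declarative study orchestration: instruments -> MR -> coloc -> mediation.

A single config (YAML mapping or :class:`RunConfig`) lists drug-target
exposures (gene region + summary statistics), outcomes with roles
(``discovery`` / ``replication`` / ``positive_control`` / ``trait``), a
genotype reference panel, and optional biomarker-screen and mediation
settings.  The pipeline runs every exposure x outcome pair through
instrument selection, harmonization, the full MR method battery and the
sensitivity analyses; Bonferroni significance is assessed per outcome
across the drug-target family.  Exposures significant in both the
discovery and replication outcomes proceed to colocalization within the
gene region plus a flank, and (when configured) to the biomarker screen
and two-step mediation.

Every stage's inputs and outputs are persisted under the output directory
so any stage can be re-run from artifacts; reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from drugmr.coloc import ColocPriors, TraitSpec, coloc_abf, window_slice
from drugmr.instruments import (
    InstrumentSet,
    ReferencePanel,
    SelectionConfig,
    select_instruments,
)
from drugmr.mediation import bonferroni, screen_biomarkers, two_step_mediation
from drugmr.mr import egger, ivw_mre, leave_one_out, weighted_median, weighted_mode
from drugmr.sumstats import GeneRegion, SummaryRecord, harmonize, read_sumstats, write_sumstats

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "exposure", "outcome", "method", "n_snps", "b", "se", "pval",
    "or_decrease", "ci_low", "ci_high", "q", "q_pval",
    "egger_intercept", "egger_intercept_pval", "mean_f", "max_retained_r2",
    "n_loo_flagged", "significant_after_bonferroni",
]


@dataclass
class ExposureSpec:
    name: str
    sumstats: str
    region: GeneRegion | None = None
    preset: str = "cis"  # cis | genome_wide
    p_threshold: float | None = None
    window_kb: float | None = None
    r2_threshold: float | None = None

    def selection_config(self) -> SelectionConfig:
        if self.preset == "cis":
            if self.region is None:
                raise ValueError(f"exposure {self.name}: cis preset requires a gene region")
            cfg = SelectionConfig.cis(self.region)
        elif self.preset == "genome_wide":
            cfg = SelectionConfig.genome_wide()
        else:
            raise ValueError(f"exposure {self.name}: unknown preset {self.preset!r}")
        overrides = {}
        if self.p_threshold is not None:
            overrides["p_threshold"] = self.p_threshold
        if self.window_kb is not None:
            overrides["window_kb"] = self.window_kb
        if self.r2_threshold is not None:
            overrides["r2_threshold"] = self.r2_threshold
        if overrides:
            import dataclasses as _dc

            cfg = _dc.replace(cfg, **overrides)
        return cfg


@dataclass
class OutcomeSpec:
    name: str
    sumstats: str
    trait_type: str = "case_control"
    role: str = "discovery"  # discovery | replication | positive_control | trait


@dataclass
class RunConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    panel: str
    out_dir: str
    seed: int = 0
    alpha_family: float = 0.05
    n_targets: int | None = None
    methods: tuple[str, ...] = ("ivw_mre", "egger", "weighted_median", "weighted_mode")
    n_boot: int = 1000
    coloc_enabled: bool = True
    coloc_flank_kb: float = 500.0
    require_both_datasets: bool = True
    biomarker_manifest: str | None = None
    biomarker_alpha: float = 0.05
    biomarker_family_size: int | None = None
    mediator_p_threshold: float = 5e-8
    mediator_r2_threshold: float = 0.001

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ValueError("config must list at least one exposure")
        if not self.outcomes:
            raise ValueError("config must list at least one outcome")

    @property
    def family_size(self) -> int:
        return self.n_targets if self.n_targets is not None else len(self.exposures)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        exposures = []
        for e in raw.get("exposures", []):
            region = e.get("region")
            if isinstance(region, str):
                region = GeneRegion.from_string(region, gene=e["name"])
            elif isinstance(region, dict):
                region = GeneRegion(**region)
            exposures.append(
                ExposureSpec(
                    name=e["name"], sumstats=e["sumstats"], region=region,
                    preset=e.get("preset", "cis"),
                    p_threshold=e.get("p_threshold"),
                    window_kb=e.get("window_kb"),
                    r2_threshold=e.get("r2_threshold"),
                )
            )
        outcomes = [
            OutcomeSpec(
                name=o["name"], sumstats=o["sumstats"],
                trait_type=o.get("trait_type", "case_control"),
                role=o.get("role", "discovery"),
            )
            for o in raw.get("outcomes", [])
        ]
        kw = {
            k: raw[k]
            for k in (
                "seed", "alpha_family", "n_targets", "n_boot", "coloc_enabled",
                "coloc_flank_kb", "require_both_datasets", "biomarker_manifest",
                "biomarker_alpha", "biomarker_family_size",
                "mediator_p_threshold", "mediator_r2_threshold",
            )
            if k in raw
        }
        return cls(exposures=exposures, outcomes=outcomes, panel=raw["panel"],
                   out_dir=raw["out_dir"], **kw)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    coloc: dict[str, dict]
    mediation: pd.DataFrame | None
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_panel(path: str | Path) -> ReferencePanel:
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return ReferencePanel.from_vcf(p)
    return ReferencePanel.from_dosage_file(p)


def _float_or_none(x) -> float | None:
    return None if x is None else float(x)


def _mr_rows(
    exposure: str,
    outcome: str,
    hset,
    instruments: InstrumentSet,
    methods: tuple[str, ...],
    n_boot: int,
    seed: int,
) -> list[dict]:
    rows = []
    j = len(hset)
    egger_int = egger_int_p = None
    if "egger" in methods and j >= 3:
        egg_est, extras = egger(hset)
        egger_int, egger_int_p = extras.intercept, extras.intercept_pval
    n_flagged = None
    if j >= 2:
        n_flagged = sum(r.flagged for r in leave_one_out(hset))
    for method in methods:
        if method == "ivw_mre":
            est = ivw_mre(hset)
        elif method == "egger":
            if j < 3:
                continue
            est = egg_est
        elif method == "weighted_median":
            if j < 3:
                continue
            est = weighted_median(hset, n_boot=n_boot, seed=seed)
        elif method == "weighted_mode":
            if j < 3:
                continue
            est = weighted_mode(hset, n_boot=n_boot, seed=seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "exposure": exposure, "outcome": outcome, "method": method,
                "n_snps": est.n_snps, "b": est.b, "se": est.se, "pval": est.pval,
                "or_decrease": est.or_decrease, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "q": _float_or_none(est.q), "q_pval": _float_or_none(est.q_pval),
                "egger_intercept": egger_int, "egger_intercept_pval": egger_int_p,
                "mean_f": instruments.mean_f, "max_retained_r2": instruments.max_retained_r2,
                "n_loo_flagged": n_flagged,
                "significant_after_bonferroni": False,
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study flow; see the module docstring for the stages.

    Per-pair errors are recorded in ``failures`` and do not abort the other
    pairs.
    """
    out_dir = Path(config.out_dir)
    for sub in ("instruments", "harmonized", "coloc", "logs"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    _setup_file_log(out_dir / "logs" / "run.log")
    logger.info("run_pipeline: seed=%d, %d exposure(s) x %d outcome(s), family size %d",
                config.seed, len(config.exposures), len(config.outcomes), config.family_size)

    panel = _load_panel(config.panel)
    threshold = bonferroni(config.alpha_family, config.family_size)
    rows: list[dict] = []
    failures: list[str] = []
    instruments_cache: dict[tuple[str, str], InstrumentSet] = {}
    exposure_data: dict[str, list[SummaryRecord]] = {}
    outcome_data: dict[str, list[SummaryRecord]] = {}

    for exp in config.exposures:
        exposure_data[exp.name] = read_sumstats(exp.sumstats)
    for out in config.outcomes:
        outcome_data[out.name] = read_sumstats(out.sumstats)

    for exp in config.exposures:
        for out in config.outcomes:
            pair = f"{exp.name}->{out.name}"
            try:
                iv = select_instruments(
                    exposure_data[exp.name], exp.selection_config(), panel,
                    outcome_sumstats=outcome_data[out.name],
                )
                instruments_cache[(exp.name, out.name)] = iv
                write_sumstats(iv.records, out_dir / "instruments" / f"{exp.name}__{out.name}.tsv")
                hset = harmonize(iv.records, outcome_data[out.name])
                if len(hset) == 0:
                    raise ValueError("no instruments survive harmonization")
                hset.write_tsv(out_dir / "harmonized" / f"{exp.name}__{out.name}.tsv")
                rows.extend(
                    _mr_rows(exp.name, out.name, hset, iv, config.methods, config.n_boot, config.seed)
                )
                logger.info("%s: %d instruments, mean F %.1f", pair, len(iv), iv.mean_f)
            except Exception as exc:  # noqa: BLE001 - per-pair isolation is the contract
                logger.error("%s: stage failed: %s", pair, exc)
                failures.append(f"{pair}: {exc}")

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not report.empty:
        sig = (report["method"] == "ivw_mre") & (report["pval"] < threshold)
        sig_pairs = set(zip(report.loc[sig, "exposure"], report.loc[sig, "outcome"]))
        report["significant_after_bonferroni"] = [
            (e, o) in sig_pairs for e, o in zip(report["exposure"], report["outcome"])
        ]
    else:
        sig_pairs = set()

    # colocalization gate: significant in every discovery AND replication outcome
    gate_roles = ("discovery", "replication")
    gate_outcomes = [o for o in config.outcomes if o.role in gate_roles]
    surviving: list[ExposureSpec] = []
    for exp in config.exposures:
        if not config.require_both_datasets:
            hits = [o for o in gate_outcomes if (exp.name, o.name) in sig_pairs]
            passed = bool(hits)
        else:
            passed = bool(gate_outcomes) and all(
                (exp.name, o.name) in sig_pairs for o in gate_outcomes
            )
        if passed:
            surviving.append(exp)

    coloc_results: dict[str, dict] = {}
    if config.coloc_enabled:
        for exp in surviving:
            if exp.region is None:
                continue
            for out in gate_outcomes:
                key = f"{exp.name}__{out.name}"
                try:
                    t1 = window_slice(exposure_data[exp.name], exp.region, config.coloc_flank_kb)
                    t2 = window_slice(outcome_data[out.name], exp.region, config.coloc_flank_kb)
                    res = coloc_abf(
                        t1, t2,
                        spec1=TraitSpec("quantitative"),
                        spec2=TraitSpec(out.trait_type),
                        priors=ColocPriors(),
                    )
                    coloc_results[key] = res.to_dict()
                    (out_dir / "coloc" / f"{key}.json").write_text(
                        json.dumps(res.to_dict(), indent=2, sort_keys=True)
                    )
                    logger.info("coloc %s: PP.H4 = %.4f, conditional = %s",
                                key, res.pp["H4"], res.conditional_h4)
                except Exception as exc:  # noqa: BLE001
                    logger.error("coloc %s failed: %s", key, exc)
                    failures.append(f"coloc {key}: {exc}")

    mediation_df = None
    if config.biomarker_manifest and surviving:
        mediation_df = _biomarker_and_mediation(
            config, surviving, exposure_data, outcome_data, panel, instruments_cache, failures
        )
        if mediation_df is not None:
            mediation_df.to_csv(out_dir / "mediation.tsv", sep="\t", index=False)

    report.to_csv(out_dir / "report.tsv", sep="\t", index=False, float_format="%.10g")
    logger.info("run_pipeline: wrote %d report rows, %d failure(s)", len(report), len(failures))
    return PipelineResult(report=report, coloc=coloc_results, mediation=mediation_df,
                          failures=failures)


def _biomarker_and_mediation(
    config: RunConfig,
    surviving: list[ExposureSpec],
    exposure_data: dict[str, list[SummaryRecord]],
    outcome_data: dict[str, list[SummaryRecord]],
    panel: ReferencePanel,
    instruments_cache: dict,
    failures: list[str],
) -> pd.DataFrame | None:
    manifest = pd.read_csv(config.biomarker_manifest, sep="\t")
    biomarkers = {
        str(r["name"]): read_sumstats(str(r["sumstats"])) for _, r in manifest.iterrows()
    }
    discovery = [o for o in config.outcomes if o.role == "discovery"]
    if not discovery:
        discovery = config.outcomes[:1]
    out = discovery[0]
    rows = []
    for exp in surviving:
        iv = instruments_cache.get((exp.name, out.name))
        if iv is None:
            continue
        screen = screen_biomarkers(
            iv, biomarkers, alpha_family=config.biomarker_alpha,
            family_size=config.biomarker_family_size,
        )
        logger.info("%s biomarker screen: %d/%d pass (threshold %.3g; %d elevated, %d reduced)",
                    exp.name, screen.n_passed, screen.family_size,
                    screen.bonferroni_alpha, screen.n_elevated, screen.n_reduced)
        b0_est = ivw_mre(harmonize(iv.records, outcome_data[out.name]))
        for name, passed in screen.passed.items():
            if not passed:
                continue
            try:
                b1_est = screen.estimates[name]
                med_iv = select_instruments(
                    biomarkers[name],
                    SelectionConfig.genome_wide(
                        p_threshold=config.mediator_p_threshold,
                        r2_threshold=config.mediator_r2_threshold,
                    ),
                    panel,
                    outcome_sumstats=outcome_data[out.name],
                )
                b2_est = ivw_mre(harmonize(med_iv.records, outcome_data[out.name]))
                med = two_step_mediation(
                    b0_est.b, b0_est.se, b1_est.b, b1_est.se, b2_est.b, b2_est.se
                )
                rows.append(
                    {
                        "exposure": exp.name, "outcome": out.name, "mediator": name,
                        "b0": med.b0, "se0": med.se0, "b1": med.b1, "se1": med.se1,
                        "b2": med.b2, "se2": med.se2,
                        "indirect": med.indirect, "se_indirect": med.se_indirect,
                        "direct": med.direct,
                        "proportion": med.proportion, "se_proportion": med.se_proportion,
                        "pval_indirect": med.pval_indirect,
                        "n_snps_mediator": len(med_iv),
                    }
                )
            except Exception as exc:  # noqa: BLE001
                logger.error("mediation %s via %s failed: %s", exp.name, name, exc)
                failures.append(f"mediation {exp.name} via {name}: {exc}")
    return pd.DataFrame(rows) if rows else None


def forest_table(report: pd.DataFrame) -> pd.DataFrame:
    """Long-format table ordered for forest-plot rendering.

    Rows grouped by outcome then exposure; OR and CI formatted to three
    decimals as ``OR (low-high)``.
    """
    if report.empty:
        raise ValueError("report is empty")
    df = report.sort_values(["outcome", "exposure", "method"], kind="stable").reset_index(drop=True)
    df = df.assign(
        or_ci=[
            f"{o:.3f} ({lo:.3f}-{hi:.3f})"
            for o, lo, hi in zip(df["or_decrease"], df["ci_low"], df["ci_high"])
        ],
        pval=[f"{p:.3g}" for p in df["pval"]],
    )
    return df[["outcome", "exposure", "method", "n_snps", "or_ci", "pval",
               "significant_after_bonferroni"]]


def _setup_file_log(path: Path) -> None:
    root = logging.getLogger("drugmr")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
    root.setLevel(logging.INFO)
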