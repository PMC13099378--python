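"""End-to-end orchestration: simulate/load -> exposures -> prep -> models ->
meta -> functional curves, with a run manifest and a text report.

All interchange is tab-delimited tables plus a JSON manifest, and every
stochastic stage receives an explicit seed derived from the run seed, so a
run is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import exposure as expo
from . import funreg as fr
from . import meta as meta_mod
from . import microbiome as micro
from . import models as mod
from . import synthetic as synth

logger = logging.getLogger("abxgut")

DIVERSITY_METRICS = ("shannon", "richness", "inv_simpson")


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    synthetic: bool = True
    sim: synth.SimConfig | None = None
    input_dir: str | None = None          # non-synthetic mode: TSV inputs
    covariates: str = "full"              # "basic" | "full"
    washout_days: int = 30
    rarefaction_depth: int | None = None  # None = per-cohort min row total
    prevalence_threshold: float = 0.02
    prevalence_mode: str = "pooled"
    fdr_level: float = 0.05
    emm_grid_max: int = 4
    funreg_n_basis: int = 6
    funreg_bootstrap: int = 100
    run_species: bool = True
    run_emm: bool = True
    run_interactions: bool = True
    run_funreg: bool = True
    run_negative_control: bool = True
    funreg_metrics: tuple[str, ...] = DIVERSITY_METRICS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            for key in ("n_per_cohort",):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "age_ranges" in sim:
                sim["age_ranges"] = tuple(tuple(a) for a in sim["age_ranges"])
            raw["sim"] = synth.SimConfig(**sim)
        if "funreg_metrics" in raw:
            raw["funreg_metrics"] = tuple(raw["funreg_metrics"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["n_per_cohort"] = list(self.sim.n_per_cohort)
            d["sim"]["age_ranges"] = [list(a) for a in self.sim.age_ranges]
        d["funreg_metrics"] = list(self.funreg_metrics)
        return d


@dataclass
class StudyResults:
    """All result tables of one run."""

    config: RunConfig
    manifest: dict
    exclusion_report: pd.DataFrame
    exposures: expo.Exposures
    diversity_cohort: pd.DataFrame   # long per-cohort results
    diversity_meta: pd.DataFrame     # pooled with q
    species_cohort: pd.DataFrame | None = None
    species_meta: pd.DataFrame | None = None
    emm: dict = field(default_factory=dict)              # metric -> period -> EmmGrid
    interactions: pd.DataFrame | None = None
    negative_control: pd.DataFrame | None = None
    curves: dict = field(default_factory=dict)           # metric -> class -> curve
    curve_tables: pd.DataFrame | None = None
    truth: synth.GroundTruth | None = None


def _load_inputs(config: RunConfig):
    if config.synthetic:
        sim = config.sim or synth.SimConfig(seed=config.seed)
        data = synth.simulate(sim)
        return data.participants, data.records, data.counts, data.truth
    if not config.input_dir:
        raise ValueError("non-synthetic mode requires input_dir")
    root = pathlib.Path(config.input_dir)
    for name in ("participants.tsv", "register.tsv"):
        if not (root / name).exists():
            raise ValueError(f"missing required input {root / name}")
    participants = pd.read_csv(
        root / "participants.tsv", sep="\t", index_col="participant_id",
        parse_dates=["visit1_date", "visit2_date", "sampling_date"],
    )
    if "family_id" in participants:
        participants["family_id"] = participants["family_id"].fillna("")
    records = pd.read_csv(root / "register.tsv", sep="\t", parse_dates=["dispense_date"])
    counts = []
    for cohort in sorted(participants["cohort"].unique()):
        path = root / f"counts_{cohort}.tsv"
        if not path.exists():
            raise ValueError(f"missing count table {path}")
        counts.append(pd.read_csv(path, sep="\t", index_col=0))
    return participants, records, pd.concat(counts), None


def _cohort_group(participants: pd.DataFrame, cohort: str) -> str | None:
    """Family grouping column when the cohort has family structure."""
    sub = participants[participants["cohort"] == cohort]
    fams = sub["family_id"].fillna("").astype(str)
    has = (fams != "") & (fams.str.lower() != "nan")
    return "family_id" if has.all() and len(sub) > 0 and fams.nunique() < len(sub) else None


def run_study(config: RunConfig) -> StudyResults:
    """Execute the full pipeline; any stage failure aborts with its name."""
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    rng_seed = config.seed

    def stage(name):
        logger.info("stage: %s", name)
        return name

    participants, records, counts, truth = _load_inputs(config)
    manifest["stages"]["input"] = {
        "participants": len(participants), "records": len(records),
        "species": counts.shape[1],
    }

    stage("exclusions")
    report, eligible = expo.apply_exclusions(
        participants, records, washout_days=config.washout_days
    )
    part = participants.loc[eligible]
    manifest["stages"]["exclusions"] = {
        "excluded": int(len(participants) - len(eligible)),
        "eligible": int(len(eligible)),
        "by_rule": report["rule"].value_counts().to_dict(),
    }

    stage("exposures")
    ex = expo.build_exposures(part, records)
    data = part.join(ex.counts)
    present_terms = [c for c in expo.EXPOSURE_COLUMNS if (data[c] > 0).any()]
    dropped_terms = sorted(set(expo.EXPOSURE_COLUMNS) - set(present_terms))
    if dropped_terms:
        logger.info("exposure terms with no exposed participants dropped: %s", dropped_terms)
    manifest["stages"]["exposures"] = {
        "terms": len(present_terms), "dropped_empty_terms": dropped_terms,
    }

    stage("microbiome_prep")
    cohorts = sorted(part["cohort"].unique())
    cohort_counts = {c: counts.loc[part.index[part["cohort"] == c]] for c in cohorts}
    relabunds = {c: micro.relative_abundance(t) for c, t in cohort_counts.items()}
    retained = micro.prevalence_filter(
        list(relabunds.values()), threshold=config.prevalence_threshold,
        mode=config.prevalence_mode,
    )
    bundles = {}
    for metric in DIVERSITY_METRICS:
        data[metric] = np.nan
    for i, c in enumerate(cohorts):
        depth = config.rarefaction_depth
        if depth is None:
            depth = int(cohort_counts[c].sum(axis=1).min())
        bundles[c] = micro.prepare_cohort(
            cohort_counts[c], retained, depth=depth, seed=rng_seed + 100 + i
        )
        data.loc[bundles[c].diversity.index, list(DIVERSITY_METRICS)] = (
            bundles[c].diversity[list(DIVERSITY_METRICS)]
        )
    manifest["stages"]["prep"] = {
        "retained_species": len(retained),
        "depths": {c: int(bundles[c].rarefied.sum(axis=1).iloc[0]) for c in cohorts},
    }

    stage("diversity_models")
    div_rows = []
    for c in cohorts:
        sub = data[data["cohort"] == c]
        group = _cohort_group(part, c)
        terms = [t for t in present_terms if (sub[t] > 0).any()]
        for metric in DIVERSITY_METRICS:
            res = mod.fit_association(
                sub, metric, terms, covariates=config.covariates, group=group
            )
            t = res.table()
            t.insert(0, "outcome", metric)
            t.insert(1, "cohort", c)
            div_rows.append(t)
    diversity_cohort = pd.concat(div_rows, ignore_index=True)
    diversity_meta = meta_mod.meta_table(diversity_cohort, by=["outcome", "term"])
    diversity_meta["q"] = meta_mod.bh_fdr(diversity_meta["p"].to_numpy())
    manifest["stages"]["diversity"] = {
        "tests": len(diversity_meta),
        "significant": int((diversity_meta["q"] < config.fdr_level).sum()),
    }

    results = StudyResults(
        config=config, manifest=manifest, exclusion_report=report, exposures=ex,
        diversity_cohort=diversity_cohort, diversity_meta=diversity_meta, truth=truth,
    )

    if config.run_species and retained:
        stage("species_models")
        sp_rows = []
        for c in cohorts:
            sub = data[data["cohort"] == c]
            clr = bundles[c].clr.loc[sub.index]
            group = _cohort_group(part, c)
            terms = [t for t in present_terms if (sub[t] > 0).any()]
            if group is None:
                t = mod.fit_many_ols(sub, clr, terms, covariates=config.covariates)
            else:
                parts_t = []
                joined = sub.join(clr)
                for spc in clr.columns:
                    res = mod.fit_association(
                        joined, spc, terms, covariates=config.covariates, group=group
                    )
                    tt = res.table()
                    tt.insert(0, "outcome", spc)
                    parts_t.append(tt)
                t = pd.concat(parts_t, ignore_index=True)
            t.insert(1, "cohort", c)
            sp_rows.append(t)
        species_cohort = pd.concat(sp_rows, ignore_index=True)
        species_meta = meta_mod.meta_table(species_cohort, by=["outcome", "term"])
        species_meta["q"] = meta_mod.bh_fdr(species_meta["p"].to_numpy())

        stage("robustness_screen")
        flagged = species_meta[
            (species_meta["q"] < config.fdr_level)
            & (species_meta["q_pvalue"] < 0.05)
        ]
        flags = {}
        for _, row in flagged.iterrows():
            cohort_data = []
            for c in cohorts:
                sub = data[data["cohort"] == c]
                if (sub[row["term"]] > 0).sum() == 0:
                    continue
                terms = [t for t in present_terms if (sub[t] > 0).any()]
                numeric, categorical = mod.covariate_sets(config.covariates)
                d = sub.join(bundles[c].clr[[row["outcome"]]]).dropna(
                    subset=[row["outcome"], *terms, *numeric, *categorical]
                )
                X = pd.concat(
                    [
                        mod.build_design(d),
                        d[terms].astype(float),
                        mod.build_design(d, numeric, categorical, intercept=False),
                    ],
                    axis=1,
                )
                X = mod._drop_constant_covariates(X, protected=terms)
                entry = {"X": X, "y": d[row["outcome"]].to_numpy()}
                if _cohort_group(part, c):
                    entry["groups"] = d["family_id"].to_numpy()
                cohort_data.append(entry)
            sr = meta_mod.dfbeta_screen(cohort_data, row["term"], alpha=0.05)
            flags[(row["outcome"], row["term"])] = sr.robust
        species_meta["robust"] = [
            flags.get((o, t), True)
            for o, t in zip(species_meta["outcome"], species_meta["term"])
        ]
        results.species_cohort = species_cohort
        results.species_meta = species_meta
        manifest["stages"]["species"] = {
            "species": len(retained),
            "tests": len(species_meta),
            "significant": int((species_meta["q"] < config.fdr_level).sum()),
            "screened": len(flags),
            "non_robust": int(sum(not v for v in flags.values())),
        }

    if config.run_emm:
        stage("emm")
        period_cols = {p: f"total_{p}" for p in expo.PERIOD_ORDER}
        grid = list(range(config.emm_grid_max + 1))
        emm = {}
        for metric in DIVERSITY_METRICS:
            emm[metric] = {}
            for per in expo.PERIOD_ORDER:
                emm[metric][per] = mod.emm_curve(
                    data, metric, period_cols, per,
                    covariates=config.covariates, grid=grid,
                )
        results.emm = emm
        manifest["stages"]["emm"] = {"grid_max": config.emm_grid_max}

    if config.run_negative_control:
        stage("negative_control")
        nc_rows = []
        for c in cohorts:
            sub = data[data["cohort"] == c]
            if (sub["post_sampling_any"] > 0).sum() <= 5:
                continue
            group = _cohort_group(part, c)
            terms = ["post_sampling_any"] + [
                t for t in present_terms if (sub[t] > 0).any()
            ]
            for metric in DIVERSITY_METRICS:
                res = mod.fit_association(
                    sub, metric, terms, covariates=config.covariates, group=group
                )
                nc_rows.append(
                    {
                        "outcome": metric, "cohort": c,
                        "beta": res.params["post_sampling_any"],
                        "se": res.bse["post_sampling_any"],
                        "p": res.pvalues["post_sampling_any"],
                    }
                )
        nc_cohort = pd.DataFrame(nc_rows)
        nc_meta = meta_mod.meta_table(nc_cohort, by=["outcome"])
        nc_meta["q"] = meta_mod.bh_fdr(nc_meta["p"].to_numpy())
        results.negative_control = nc_meta
        manifest["stages"]["negative_control"] = {
            "significant": int((nc_meta["q"] < config.fdr_level).sum())
        }

    if config.run_interactions:
        stage("interactions")
        int_rows = []
        for modifier in ("sex", "age"):
            for cls in expo.ANTIBIOTIC_CLASSES:
                cls_cols = [expo.exposure_column(cls, p) for p in expo.PERIOD_ORDER]
                ps = []
                for c in cohorts:
                    sub = data[data["cohort"] == c]
                    if not all(t in present_terms and (sub[t] > 0).any() for t in cls_cols):
                        continue
                    if not mod.interaction_eligible(sub, cls_cols, modifier):
                        logger.info(
                            "interaction %s x %s skipped in %s: eligibility rule",
                            cls, modifier, c,
                        )
                        continue
                    group = _cohort_group(part, c)
                    terms = [t for t in present_terms if (sub[t] > 0).any()]
                    p = mod.interaction_lrt(
                        sub, "shannon", cls_cols, modifier, terms,
                        covariates=config.covariates, group=group,
                    )
                    ps.append(p)
                if ps:
                    int_rows.append(
                        {
                            "abx_class": cls, "modifier": modifier,
                            "n_cohorts": len(ps),
                            "p": meta_mod.fisher_combine(ps),
                        }
                    )
        interactions = pd.DataFrame(int_rows)
        if len(interactions):
            interactions["q"] = meta_mod.bh_fdr(interactions["p"].to_numpy())
        results.interactions = interactions
        manifest["stages"]["interactions"] = {"tests": len(interactions)}

    if config.run_funreg:
        stage("functional_regression")
        numeric, categorical = mod.covariate_sets(config.covariates)
        curve_frames = []
        curves: dict = {}
        for metric in config.funreg_metrics:
            per_cohort: dict[str, list[fr.FunctionalCurve]] = {}
            for i, c in enumerate(cohorts):
                sub = data[data["cohort"] == c].dropna(
                    subset=[metric, *numeric, *categorical]
                )
                rows = ex.ids.get_indexer(sub.index)
                monthly = {
                    cls: ex.monthly[rows, j, :]
                    for j, cls in enumerate(expo.ANTIBIOTIC_CLASSES)
                }
                monthly = fr.merge_rare_classes(monthly)
                Xc = pd.concat(
                    [mod.build_design(sub),
                     mod.build_design(sub, numeric, categorical, intercept=False)],
                    axis=1,
                )
                Xc = mod._drop_constant_covariates(Xc, protected=[])
                y = sub[metric].to_numpy(dtype=float)
                fams = (
                    sub["family_id"].to_numpy() if _cohort_group(part, c) else None
                )
                fit = fr.fit_scalar_on_function(
                    y, monthly, Xc.to_numpy(), n_basis=config.funreg_n_basis
                )
                ses = fr.bootstrap_pointwise_se(
                    y, monthly, Xc.to_numpy(), n_boot=config.funreg_bootstrap,
                    seed=rng_seed + 500 + i, families=fams,
                    n_basis=config.funreg_n_basis,
                )
                for cls, curve in fit.curves.items():
                    curve.se = ses[cls]
                    per_cohort.setdefault(cls, []).append(curve)
                tab = fr.curve_table(fit.curves, cohort=c)
                tab.insert(0, "metric", metric)
                curve_frames.append(tab)
            curves[metric] = {
                cls: fr.meta_curves(cs) for cls, cs in per_cohort.items()
            }
            tab = fr.curve_table(curves[metric], cohort="pooled")
            tab.insert(0, "metric", metric)
            curve_frames.append(tab)
        results.curves = curves
        results.curve_tables = pd.concat(curve_frames, ignore_index=True)
        manifest["stages"]["funreg"] = {
            "n_basis": config.funreg_n_basis, "bootstrap": config.funreg_bootstrap,
        }

    return results


def write_results(results: StudyResults, outdir) -> None:
    """Serialize all result tables (TSV) and the manifest (JSON)."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.exclusion_report.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    results.exposures.counts.to_csv(out / "exposure_counts.tsv", sep="\t")
    results.diversity_cohort.to_csv(out / "diversity_cohort.tsv", sep="\t", index=False)
    results.diversity_meta.to_csv(out / "diversity_meta.tsv", sep="\t", index=False)
    if results.species_meta is not None:
        results.species_cohort.to_csv(out / "species_cohort.tsv", sep="\t", index=False)
        results.species_meta.to_csv(out / "species_meta.tsv", sep="\t", index=False)
    if results.emm:
        rows = []
        for metric, by_period in results.emm.items():
            for per, grid in by_period.items():
                for c, e, s in zip(grid.grid, grid.emm, grid.se):
                    rows.append((metric, per, int(c), e, s))
        pd.DataFrame(
            rows, columns=["metric", "period", "courses", "emm", "se"]
        ).to_csv(out / "emm.tsv", sep="\t", index=False)
    if results.interactions is not None:
        results.interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
    if results.negative_control is not None:
        results.negative_control.to_csv(
            out / "negative_control.tsv", sep="\t", index=False
        )
    if results.curve_tables is not None:
        results.curve_tables.to_csv(out / "functional_curves.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(results.manifest, fh, indent=2, default=str)


def summarize(results: StudyResults) -> str:
    """Human-readable run report."""
    lines = ["=== study summary ==="]
    m = results.manifest["stages"]
    lines.append(
        f"participants: {m['input']['participants']} "
        f"({m['exclusions']['eligible']} eligible after "
        f"{m['exclusions']['excluded']} exclusions)"
    )
    lines.append(f"exclusions by rule: {m['exclusions']['by_rule']}")
    dm = results.diversity_meta
    sig = dm[dm["q"] < results.config.fdr_level]
    lines.append(
        f"diversity: {len(sig)}/{len(dm)} class-period-metric associations at "
        f"FDR {results.config.fdr_level:.0%}"
    )
    for _, r in sig.nsmallest(5, "q").iterrows():
        lines.append(
            f"  {r['outcome']} ~ {r['term']}: beta={r['beta']:.2f} "
            f"(se {r['se']:.2f}), q={r['q']:.2e}, I2={r['i2']:.0f}%"
        )
    if results.species_meta is not None:
        sm = results.species_meta
        sig_sp = sm[sm["q"] < results.config.fdr_level]
        if len(sig_sp):
            tally = (
                sig_sp.groupby(sig_sp["term"].str.rsplit("_", n=1).str[0])
                .size()
                .sort_values(ascending=False)
            )
            lines.append(
                f"species: {len(sig_sp)} significant associations; by class: "
                + ", ".join(f"{k}={v}" for k, v in tally.items())
            )
            if "robust" in sm:
                lines.append(
                    f"  non-robust after influence screen: "
                    f"{int((~sm.loc[sig_sp.index, 'robust']).sum())}"
                )
        else:
            lines.append("species: no significant associations")
    else:
        lines.append("species stage skipped")
    if results.negative_control is not None:
        nc = results.negative_control
        lines.append(
            f"negative control (post-sampling use): "
            f"{int((nc['q'] < results.config.fdr_level).sum())}/{len(nc)} significant"
        )
    het = dm[dm["q_pvalue"] < 0.05]
    lines.append(
        f"heterogeneity: {len(het)}/{len(dm)} diversity terms with Cochran Q p<0.05; "
        f"median I2 {dm['i2'].median():.0f}%"
    )
    return "\n".join(lines)
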