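"""End-to-end pipeline: simulate -> preprocess -> score -> stats ->
language -> predict -> assoc -> report.

Each stage reads its inputs from and writes its outputs to a single run
directory, so stages can be re-run individually; a JSON manifest records
the configuration, per-stage seeds, and SHA-256 hashes of every produced
file.  Two profiles are provided: ``fast`` (small topic model and
embedding width; minutes on a laptop) and ``paper`` (200 topics, 750 LDA
iterations, 1536-wide embeddings, 20000 permutations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc_mod
from . import language as lang
from . import prediction as pred
from . import preprocess as pp
from . import scoring
from . import stats as st
from .synthetic_data import CohortConfig, simulate_cohort, write_cohort

__all__ = ["RunConfig", "PROFILES", "run", "report", "load_config"]

PROFILES = {
    "fast": dict(lda_k=25, lda_iters=150, stop_top=20, embed_dim=256,
                 n_perm=2000),
    "paper": dict(lda_k=200, lda_iters=750, stop_top=75, embed_dim=1536,
                  n_perm=20000),
}

ALL_STAGES = ("simulate", "preprocess", "score", "stats", "language",
              "predict", "assoc", "report")


@dataclass
class RunConfig:
    outdir: str = "emaswb_run"
    profile: str = "fast"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple[str, ...] = ALL_STAGES
    stage_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        defaults = {name: self.seed + 1000 + i for i, name in enumerate(ALL_STAGES)}
        self.stage_seeds = {**defaults, **self.stage_seeds}

    @property
    def params(self) -> dict:
        return PROFILES[self.profile]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML or JSON file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    cohort = CohortConfig(**raw.pop("cohort", {}))
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(cohort=cohort, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _out(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage inputs missing from {out}: {missing}; run the upstream "
            "stage first")


# -- stages ----------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    cohort = dataclasses.replace(cfg.cohort, seed=cfg.stage_seeds["simulate"])
    baseline, ema = simulate_cohort(cohort)
    write_cohort(baseline, ema, out)
    return ["baseline.csv", "ema.csv"]


def stage_preprocess(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "ema.csv")
    ema = pd.read_csv(out / "ema.csv", keep_default_na=False,
                      na_values=[""], dtype={"alone": str})
    ema["stress"] = pd.to_numeric(ema["stress"], errors="coerce")
    ema["burnout"] = pd.to_numeric(ema["burnout"], errors="coerce")
    days = pp.build_day_records(ema)
    days, report_d = pp.apply_exclusions(days)
    pairs = pp.lag_tonight(days)
    af = pp.alone_fraction(days)
    days.to_csv(out / "days.csv", index=False, na_rep="NA")
    pairs.to_csv(out / "tonight_pairs.csv", index=False, na_rep="NA")
    af.to_csv(out / "alone_fraction.csv", index=False, na_rep="NA")
    (out / "exclusion_report.json").write_text(json.dumps(report_d, indent=2))
    return ["days.csv", "tonight_pairs.csv", "alone_fraction.csv",
            "exclusion_report.json"]


def _read_days(out: Path) -> pd.DataFrame:
    days = pd.read_csv(out / "days.csv", keep_default_na=False, na_values=[""],
                       dtype={"alone": str})
    for c in ("valence", "stress", "burnout", "drinks_yesterday",
              "anscombe_drinks"):
        days[c] = pd.to_numeric(days[c], errors="coerce")
    return days


def stage_score(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "days.csv", "baseline.csv")
    days = _read_days(out)
    baseline = pd.read_csv(out / "baseline.csv")
    persons = scoring.score_persons(days, baseline)
    persons.to_csv(out / "person_swb.csv", index=False, na_rep="NA")

    rel: dict = {}
    for col, key in (("valence", "icc_valence"), ("stress", "icc_stress"),
                     ("burnout", "icc_burnout")):
        ok = days.dropna(subset=[col])
        rel[key] = scoring.icc_1(ok[col], ok["participant_id"])
    day_items = scoring.score_days(days)[["valence", "stress", "burnout"]].dropna()
    items = np.column_stack([day_items["valence"], -day_items["stress"],
                             -day_items["burnout"]])
    rel["momentary_alpha_days"] = scoring.cronbach_alpha(items)
    pm = days.groupby("participant_id")[["valence", "stress", "burnout"]].mean() \
        .dropna()
    rel["momentary_alpha_persons"] = scoring.cronbach_alpha(
        np.column_stack([pm["valence"], -pm["stress"], -pm["burnout"]]))
    for wave_a, wave_b in ((1, 2), (2, 3)):
        piv = baseline.pivot_table(index="participant_id", columns="wave",
                                   values="audit")
        if wave_a in piv.columns and wave_b in piv.columns:
            both = piv[[wave_a, wave_b]].dropna()
            if len(both) >= 3:
                rel[f"audit_retest_w{wave_a}{wave_b}"] = scoring.test_retest(
                    both[wave_a], both[wave_b])
    (out / "reliability_report.json").write_text(
        json.dumps({k: round(float(v), 4) for k, v in rel.items()}, indent=2))
    return ["person_swb.csv", "reliability_report.json"]


def stage_stats(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "days.csv", "tonight_pairs.csv", "person_swb.csv",
             "alone_fraction.csv")
    days = scoring.score_days(_read_days(out))
    pairs = pp.lag_tonight(days)
    persons = pd.read_csv(out / "person_swb.csv")
    af = pd.read_csv(out / "alone_fraction.csv")
    n_perm = cfg.params["n_perm"]
    seed = cfg.stage_seeds["stats"]

    rows = []
    # between-person: SWB/AUDIT/loneliness vs mean drinks and alone fraction
    pm = days.groupby("participant_id")["anscombe_drinks"].mean() \
        .rename("mean_drinks")
    tbl = persons.merge(pm, on="participant_id") \
        .merge(af[af["included"]][["participant_id", "alone_fraction"]],
               on="participant_id", how="left")
    for var1 in ("swb", "audit", "ucla3"):
        for var2 in ("mean_drinks", "alone_fraction"):
            ok = tbl.dropna(subset=[var1, var2])
            if len(ok) < 4:
                continue
            r = float(np.corrcoef(ok[var1], ok[var2])[0, 1])
            p = float(__import__("scipy.stats", fromlist=["pearsonr"])
                      .pearsonr(ok[var1], ok[var2]).pvalue)
            rows.append((var1, var2, "between", r, p, len(ok)))

    # within-person: momentary SWB vs drinks tonight / yesterday; alone days
    def within_row(frame, xcol, ycol, label, ylabel):
        ok = frame.dropna(subset=[xcol, ycol]).copy()
        cent = st.within_center(ok, [xcol, ycol])
        r = st.fixed_effect_r(cent[xcol], cent[ycol])
        p = st.permutation_p(cent[xcol], cent[ycol],
                             ok["participant_id"].to_numpy(),
                             n_perm=n_perm, seed=seed)
        rows.append(("momentary_swb", ylabel, label, r, p, len(ok)))

    within_row(pairs, "momentary_swb", "anscombe_tonight", "within_tonight",
               "drinks")
    within_row(days, "momentary_swb", "anscombe_drinks", "within_yesterday",
               "drinks")
    p2 = pairs[pairs["alone_tonight"].isin(["alone", "others"])].copy()
    p2["alone01"] = (p2["alone_tonight"] == "alone").astype(float)
    if len(p2) > 30:
        within_row(p2, "momentary_swb", "alone01", "within_tonight",
                   "drinking_alone")
    d2 = days[days["alone"].isin(["alone", "others"])].copy()
    d2["alone01"] = (d2["alone"] == "alone").astype(float)
    if len(d2) > 30:
        within_row(d2, "momentary_swb", "alone01", "within_yesterday",
                   "drinking_alone")

    fig1 = pd.DataFrame(rows, columns=["var1", "var2", "level", "r", "p", "n"])
    fig1.to_csv(out / "fig1_correlations.csv", index=False)

    # Table-1 style: SWB by drinking-alone group
    grp = af.merge(persons[["participant_id", "swb"]], on="participant_id")
    drinkers = days.groupby("participant_id")["drinks_yesterday"].max()
    never = drinkers[drinkers == 0].index
    w23 = set(days.loc[days["alone"].isin(["alone", "others", "NA"]) &
                       (days["wave"] >= 2), "participant_id"])
    scored = persons.dropna(subset=["swb"]).set_index("participant_id")["swb"]
    groups = {}
    inc = grp[grp["included"]]
    groups["always_with_others"] = inc[inc["alone_fraction"] == 0]["participant_id"]
    groups["always_drinking_alone"] = inc[inc["alone_fraction"] == 1]["participant_id"]
    groups["sometimes_drinks_alone"] = inc[
        (inc["alone_fraction"] > 0) & (inc["alone_fraction"] < 1)]["participant_id"]
    groups["never_drinking"] = pd.Series(sorted(set(never) & w23))
    pool_ids = sorted(set().union(*[set(v) for v in groups.values()]) &
                      set(scored.index))
    pool = scoring.zscore(scored.loc[pool_ids].to_numpy(), ddof=0)
    pooled = pd.Series(pool, index=pool_ids)
    grand = float(pooled.mean())
    t1 = []
    for name, ids in groups.items():
        vals = pooled.reindex([i for i in ids if i in pooled.index]).dropna()
        if len(vals) < 2:
            continue
        g = st.group_deviation_test(vals, grand)
        t1.append((name, g.n, round(100 * g.n / len(pooled), 1), g.mean, g.se,
                   g.p))
    t1.append(("everyone_included", len(pooled), 100.0, grand,
               float(pooled.std(ddof=1) / np.sqrt(len(pooled))), 1.0))
    pd.DataFrame(t1, columns=["group", "n", "pct", "mean_swb", "se", "p"]) \
        .to_csv(out / "table1_groups.csv", index=False)

    # Table-2 style: standardized regression of SWB on drinking behavior
    reg_tbl = tbl.dropna(subset=["swb", "mean_drinks", "audit",
                                 "alone_fraction"])
    table2 = st.std_multiple_regression(
        reg_tbl["swb"], reg_tbl[["mean_drinks", "audit", "alone_fraction"]])
    (out / "table2_regression.json").write_text(json.dumps(table2, indent=2))
    return ["fig1_correlations.csv", "table1_groups.csv",
            "table2_regression.json"]


def stage_language(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "days.csv")
    days = _read_days(out)
    corpus = lang.build_corpus(days, level="day")
    p = cfg.params
    model = lang.fit_lda(corpus, k=p["lda_k"], stop_top=p["stop_top"],
                         iters=p["lda_iters"],
                         seed=cfg.stage_seeds["language"])
    topics = {str(j): lang.TopicModel.top_words(model, j, m=10)
              for j in range(model.k)}
    (out / "topics.json").write_text(json.dumps(
        {"stop_words": model.stop_words, "k": model.k,
         "iterations": model.iterations, "topics": topics}, indent=2))
    usage = pd.DataFrame(model.doc_topic,
                         columns=[f"topic_{j}" for j in range(model.k)])
    ids = pd.DataFrame(model.doc_ids,
                       columns=["participant_id", "wave", "day_index"])
    doc_usage = pd.concat([ids, usage], axis=1)
    doc_usage.to_csv(out / "doc_topic_usage.csv", index=False)
    person_usage = lang.person_topic_usage(model, ids["participant_id"])
    person_usage.to_csv(out / "person_topic_usage.csv")

    emb = lang.encode(corpus, encoder="synthetic", dim=p["embed_dim"],
                      seed=cfg.stage_seeds["language"],
                      vocab=cfg.cohort.vocabulary)
    np.save(out / "embeddings.npy", emb.to_numpy())
    ids.to_csv(out / "embeddings_index.csv", index=False)
    return ["topics.json", "doc_topic_usage.csv", "person_topic_usage.csv",
            "embeddings.npy", "embeddings_index.csv"]


def stage_predict(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "embeddings.npy", "embeddings_index.csv", "days.csv",
             "person_swb.csv", "alone_fraction.csv")
    X = np.load(out / "embeddings.npy")
    idx = pd.read_csv(out / "embeddings_index.csv")
    days = scoring.score_days(_read_days(out))
    persons = pd.read_csv(out / "person_swb.csv")
    af = pd.read_csv(out / "alone_fraction.csv")
    seed = cfg.stage_seeds["predict"]
    rows = []

    # between-person: person-mean embeddings predicting mean drinks,
    # alone fraction (feature selection + PCA) and SWB (convergence)
    pe = lang.person_mean_embeddings(
        pd.DataFrame(X, index=idx["participant_id"]), idx["participant_id"])
    pm = days.groupby("participant_id")["anscombe_drinks"].mean()
    targets = {
        "drinks": (pm, None),
        "drinking_alone": (af[af["included"]].set_index("participant_id")
                           ["alone_fraction"], (min(100, X.shape[1]), 20)),
        "swb": (persons.set_index("participant_id")["swb"], None),
    }
    for name, (target, reduction) in targets.items():
        common = pe.index.intersection(target.dropna().index)
        if len(common) < 30:
            continue
        Xp = pe.loc[common].to_numpy()
        yp = target.loc[common].to_numpy(float)
        plan = pred.make_cv_plan(len(common), k=10, seed=seed)
        res = pred.ridge_cv(Xp, yp, plan, reduction=reduction)
        rows.append((name, "between",
                     "embeddings+fs_pca" if reduction else "embeddings",
                     res.r, res.n))

    # within-person: day embeddings (within-centered feature-wise)
    pairs = pp.lag_tonight(days)
    key = ["participant_id", "wave", "day_index"]
    emb_df = pd.concat([idx, pd.DataFrame(X)], axis=1)
    for label, ycol in (("within_tonight", "anscombe_tonight"),
                        ("within_yesterday", "anscombe_drinks")):
        frame = pairs if label == "within_tonight" else days
        merged = frame[key + [ycol]].merge(emb_df, on=key, how="inner")
        merged = merged.dropna(subset=[ycol])
        feat_cols = [c for c in merged.columns if isinstance(c, int)]
        cent = st.within_center(merged, feat_cols + [ycol])
        groups = merged["participant_id"].to_numpy()
        plan = pred.make_cv_plan(len(merged), k=10, groups=groups, seed=seed)
        res = pred.ridge_cv(cent[feat_cols].to_numpy(),
                            cent[ycol].to_numpy(float), plan)
        rows.append(("drinks", label, "embeddings", res.r, res.n))

    fig1d = pd.DataFrame(rows, columns=["outcome", "level", "feature_set",
                                        "r", "n"])
    fig1d.to_csv(out / "fig1d_accuracies.csv", index=False)
    return ["fig1d_accuracies.csv"]


def stage_assoc(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "doc_topic_usage.csv", "person_topic_usage.csv", "days.csv",
             "person_swb.csv", "alone_fraction.csv")
    person_usage = pd.read_csv(out / "person_topic_usage.csv",
                               index_col="participant_id")
    doc_usage = pd.read_csv(out / "doc_topic_usage.csv")
    days = _read_days(out)
    persons = pd.read_csv(out / "person_swb.csv").set_index("participant_id")
    af = pd.read_csv(out / "alone_fraction.csv")
    topic_cols = [c for c in person_usage.columns if c.startswith("topic_")]

    frames = []
    pm = days.groupby("participant_id")["anscombe_drinks"].mean()
    between_targets = {
        "drinks": pm,
        "audit": persons["audit"],
        "drinking_alone": af[af["included"]].set_index("participant_id")
        ["alone_fraction"],
    }
    for name, target in between_targets.items():
        common = person_usage.index.intersection(target.dropna().index)
        cov = persons.loc[common, ["age"]].copy()
        cov["female"] = (persons.loc[common, "gender"] == "female").astype(float)
        res = assoc_mod.associate_topics(
            person_usage.loc[common, topic_cols], target.loc[common],
            covariates=cov, level="between")
        res["outcome"] = name
        frames.append(res)

    # within: day usage vs drinks tonight / yesterday
    key = ["participant_id", "wave", "day_index"]
    days2 = pp.lag_tonight(days)
    for label, frame, ycol in (("within_tonight", days2, "anscombe_tonight"),
                               ("within_yesterday", days, "anscombe_drinks")):
        merged = frame[key + [ycol]].merge(doc_usage, on=key, how="inner") \
            .dropna(subset=[ycol])
        res = assoc_mod.associate_topics(
            merged[topic_cols], merged[ycol], level="within",
            person_ids=merged["participant_id"])
        res["outcome"] = "drinks"
        res["level"] = label
        frames.append(res)

    allres = pd.concat(frames, ignore_index=True)
    allres.to_csv(out / "topic_associations.csv", index=False)

    topics_meta = json.loads((out / "topics.json").read_text())
    lines = ["# Topic-outcome associations\n"]
    for (outc, lvl), sub in allres.groupby(["outcome", "level"]):
        sig = sub[sub["bh_significant"]].sort_values("r", key=abs,
                                                     ascending=False)
        lines.append(f"\n## {outc} ({lvl}) - {len(sig)} BH-significant topics\n")
        for _, row in sig.head(10).iterrows():
            tid = row["topic"].split("_")[1]
            words = ", ".join(w for w, _ in topics_meta["topics"][tid][:6])
            lines.append(f"- r = {row['r']:+.3f}  (p = {row['p']:.2e})  "
                         f"[{words}]")
    (out / "fig_topics_report.md").write_text("\n".join(lines))
    return ["topic_associations.csv", "fig_topics_report.md"]


def stage_report(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    _require(out, "fig1_correlations.csv", "table1_groups.csv",
             "table2_regression.json")
    parts = ["# Run report\n"]
    fig1 = pd.read_csv(out / "fig1_correlations.csv")
    parts.append("\n## Correlation panel (Fig-1 style)\n")
    parts.append(fig1.to_markdown(index=False))
    if (out / "fig1d_accuracies.csv").exists():
        parts.append("\n\n## Language-based prediction accuracies "
                     "(Fig-1D style)\n")
        parts.append(pd.read_csv(out / "fig1d_accuracies.csv")
                     .to_markdown(index=False))
    t1 = pd.read_csv(out / "table1_groups.csv")
    parts.append("\n\n## Drinking-alone groups (Table-1 style)\n")
    parts.append(t1.to_markdown(index=False))
    t2 = json.loads((out / "table2_regression.json").read_text())
    parts.append("\n\n## Standardized regression (Table-2 style)\n")
    parts.append("```json\n" + json.dumps(t2, indent=2) + "\n```\n")
    (out / "report.md").write_text("\n".join(parts))
    return ["report.md"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "score": stage_score,
    "stats": stage_stats,
    "language": stage_language,
    "predict": stage_predict,
    "assoc": stage_assoc,
    "report": stage_report,
}


def run(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = _out(cfg)
    manifest: dict = {
        "profile": cfg.profile,
        "seed": cfg.seed,
        "stage_seeds": {k: v for k, v in cfg.stage_seeds.items()
                        if k in cfg.stages},
        "cohort": {k: v for k, v in dataclasses.asdict(cfg.cohort).items()
                   if isinstance(v, (int, float, str, bool))},
        "stages": {},
        "skipped": [s for s in ALL_STAGES if s not in cfg.stages],
    }
    for name in ALL_STAGES:
        if name not in cfg.stages:
            continue
        files = _STAGE_FUNCS[name](cfg)
        manifest["stages"][name] = {
            "files": {f: _sha256(out / f) for f in files},
            "seed": cfg.stage_seeds[name],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(cfg: RunConfig) -> dict:
    """Regenerate the summary report from an existing run directory."""
    stage_report(cfg)
    return json.loads((Path(cfg.outdir) / "manifest.json").read_text()) \
        if (Path(cfg.outdir) / "manifest.json").exists() else {}
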