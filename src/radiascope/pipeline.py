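"""End-to-end pipeline: simulate -> quartets -> diagnostics -> subsampling ->
rates/demography -> traits, driven by one YAML/dict config with a single
root seed fanned out into named per-stage substreams, and a manifest with
sha256 checksums of every output so reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import msc, quartets, rates, seqsim, subsampling, traits
from .tree import write_newick

__all__ = ["STAGES", "RunConfig", "run_pipeline"]

STAGES = ("simulate", "quartets", "diagnostics", "subsampling", "rates", "traits")
_DEPS = {
    "quartets": ("simulate",),
    "diagnostics": ("simulate",),
    "subsampling": ("simulate",),
    "rates": ("simulate", "quartets"),
    "traits": ("simulate",),
}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "radiascope_run",
    "stages": list(STAGES),
    "simulate": {
        "n_taxa": 10,
        "birth_rate": 0.2,
        "ne": msc.DEFAULT_NE,
        "generation_time": msc.DEFAULT_GEN_TIME,
        "rate": msc.DEFAULT_RATE,
        "n_loci": 500,
        "p_nni": 0.0,
        "collapse_fraction": 0.0,
        "hybridization": None,  # {"donor": [...], "recipient": [...], "gamma": g}
    },
    "diagnostics": {"n_loci": 20, "n_sites": 500, "n_sim": 49},
    "subsampling": {"sizes": [50, 100, 250], "n_replicates": 5},
    "traits": {"n_traits": 20, "lambda": 0.96, "sigma2": 1.0},
}


class RunConfig:
    """Validated pipeline configuration (YAML file, path or mapping)."""

    def __init__(self, source: str | Path | Mapping):
        if isinstance(source, (str, Path)):
            import yaml

            raw = yaml.safe_load(Path(source).read_text()) or {}
        else:
            raw = dict(source)
        cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
        for key, val in raw.items():
            if key in cfg and isinstance(cfg[key], dict) and isinstance(val, Mapping):
                cfg[key].update(val)
            else:
                cfg[key] = val
        unknown = set(cfg) - set(_DEFAULTS) - {"quartets", "rates"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = cfg["stages"]
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        for s in stages:
            for dep in _DEPS.get(s, ()):
                if dep not in stages:
                    raise ValueError(f"stage {s!r} requires stage {dep!r} to be enabled")
        self.cfg = cfg

    def __getitem__(self, key):
        return self.cfg[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, text: str, manifest: dict, stage: str) -> None:
    path.write_text(text)
    manifest["stages"][stage]["outputs"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig | Mapping | str | Path, dry_run: bool = False) -> dict:
    """Execute the enabled stages in dependency order and return the manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    cfg = config.cfg
    outdir = Path(cfg["outdir"])
    stages = [s for s in STAGES if s in cfg["stages"]]
    manifest: dict = {
        "seed": cfg["seed"],
        "stages": {s: {"outputs": {}} for s in stages},
        "config": cfg,
    }
    if dry_run:
        manifest["plan"] = stages
        return manifest
    outdir.mkdir(parents=True, exist_ok=True)
    streams = dict(zip(STAGES, np.random.SeedSequence(cfg["seed"]).spawn(len(STAGES))))

    state: dict[str, Any] = {}
    for stage in stages:
        fn = globals()[f"_stage_{stage}"]
        try:
            fn(cfg, streams[stage], outdir, manifest, state)
        except Exception as exc:
            manifest["stages"][stage]["error"] = str(exc)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# -- stages ----------------------------------------------------------------

def _stage_simulate(cfg, seed, outdir, manifest, state):
    p = cfg["simulate"]
    ss = seed.spawn(4)
    model = msc.simulate_species_tree(
        p["n_taxa"], p["birth_rate"], seed=ss[0],
        ne=p["ne"], gen_time=p["generation_time"], rate=p["rate"],
    )
    hyb = p.get("hybridization")
    if hyb:
        gts, rerouted = msc.simulate_hybrid_gene_trees(
            model, frozenset(hyb["donor"]), frozenset(hyb["recipient"]),
            hyb["gamma"], p["n_loci"], seed=ss[1],
        )
    else:
        gts = msc.simulate_gene_trees(model, p["n_loci"], seed=ss[1])
        rerouted = np.zeros(p["n_loci"], dtype=bool)
    gts_subs = msc.simulate_gene_trees(model, p["n_loci"], seed=ss[1], unit="subs/site")
    if p["p_nni"] or p["collapse_fraction"]:
        gts = msc.apply_gene_tree_error(gts, p["p_nni"], p["collapse_fraction"], seed=ss[2])
    truth = {
        "branches": [
            {"clade": sorted(c), "T_ma": T, "d": d, "ne": ne}
            for c, T, d, ne in model.branch_table()
        ],
        "rerouted_loci": [int(i) for i in np.nonzero(rerouted)[0]],
    }
    _write(outdir / "species_time.nwk", write_newick(model.tree) + "\n", manifest, "simulate")
    _write(
        outdir / "species_cu.nwk",
        write_newick(msc.time_to_coalescent_units(model)) + "\n",
        manifest,
        "simulate",
    )
    _write(
        outdir / "gene_trees.nwk",
        "".join(write_newick(t) + "\n" for t in gts),
        manifest,
        "simulate",
    )
    _write(
        outdir / "gene_trees_subs.nwk",
        "".join(write_newick(t) + "\n" for t in gts_subs),
        manifest,
        "simulate",
    )
    _write(outdir / "ground_truth.json", json.dumps(truth, indent=2), manifest, "simulate")
    state.update(model=model, gene_trees=gts, gene_trees_subs=gts_subs)


def _stage_quartets(cfg, seed, outdir, manifest, state):
    model: msc.SpeciesTreeModel = state["model"]
    qs = quartets.branch_quartet_frequencies(model.tree, state["gene_trees"])
    asym = quartets.asymmetry_test(qs)
    rows = []
    for b in qs:
        q1, q2, q3 = b.frequencies
        d = quartets.coalescent_branch_length(q1)
        pp = quartets.local_posterior(b)
        sub = asym[(asym["branch"] == b.branch) & (asym["comparison"] == "alt")]
        rows.append(
            {
                "branch": "|".join(sorted(b.branch)),
                "n1": b.n1, "n2": b.n2, "n3": b.n3,
                "q1": q1, "q2": q2, "q3": q3,
                "d": d.d, "saturated": d.saturated,
                "local_pp": pp[0],
                "polytomy_p": quartets.polytomy_test(b),
                "asym_p_raw": float(sub["p_raw"].iloc[0]) if len(sub) else np.nan,
                "asym_p_bh": float(sub["p_bh"].iloc[0]) if len(sub) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    _write(outdir / "branch_support.tsv", df.to_csv(sep="\t", index=False), manifest, "quartets")
    state["branch_table"] = df
    state["quartet_support"] = qs


def _stage_diagnostics(cfg, seed, outdir, manifest, state):
    p = cfg["diagnostics"]
    model = state["model"]
    sub_model = seqsim.SubstitutionModel()
    gts = state["gene_trees_subs"][: p["n_loci"]]
    ss = seed.spawn(len(gts) + 1)
    null = diag.simulate_null_statistics(
        model.tree, sub_model, p["n_sites"], p["n_sim"], ss[-1], diag.composition_chi2
    )
    rows = []
    for i, gt in enumerate(gts):
        aln = seqsim.simulate_alignment(gt, sub_model, p["n_sites"], seed=ss[i])
        stats = diag.alignment_metrics(aln)
        st = diag.stationarity_test(aln, model.tree, sub_model, null_stats=null)
        rows.append(
            {
                "locus": i,
                "length": stats.length,
                "prop_pi": stats.prop_parsimony_informative,
                "gc_mean": stats.gc_mean,
                "gc_sd": stats.gc_sd,
                "stationarity_p": st.p_value,
            }
        )
    _write(
        outdir / "locus_diagnostics.tsv",
        pd.DataFrame(rows).to_csv(sep="\t", index=False),
        manifest,
        "diagnostics",
    )


def _stage_subsampling(cfg, seed, outdir, manifest, state):
    p = cfg["subsampling"]
    design = subsampling.SubsampleDesign(
        sizes=[s for s in p["sizes"] if s <= len(state["gene_trees"])],
        n_replicates=p["n_replicates"],
        seed=int(seed.generate_state(1)[0] % (2**31)),
        reference=state["model"].tree,
    )
    table, extra = subsampling.run_locus_subsampling(state["gene_trees"], design)
    _write(outdir / "subsampling.tsv", table.to_csv(sep="\t", index=False), manifest, "subsampling")
    rec = subsampling.clade_recovery(
        extra["trees"], list(state["model"].tree.clades().values())[1:]
    )
    rec_df = pd.DataFrame(
        [
            {"clade": "|".join(sorted(c.clade)), "difficulty": c.difficulty}
            for c in rec
            if 2 <= len(c.clade) < state["model"].tree.n_taxa
        ]
    )
    _write(outdir / "clade_recovery.tsv", rec_df.to_csv(sep="\t", index=False), manifest, "subsampling")


def _stage_rates(cfg, seed, outdir, manifest, state):
    model = state["model"]
    tab = rates.concordant_branch_rates(state["gene_trees_subs"], model.tree)
    _write(
        outdir / "branch_rates.tsv",
        tab.assign(branch=tab["branch"].apply(lambda b: "|".join(sorted(b)))).to_csv(
            sep="\t", index=False
        ),
        manifest,
        "rates",
    )
    cu = msc.time_to_coalescent_units(model)
    ne_df = rates.ne_ratio(model.tree, cu, generation_time=model.gen_time.get(frozenset(model.tree.taxa)))
    _write(
        outdir / "ne_per_branch.tsv",
        ne_df.assign(branch=ne_df["branch"].apply(lambda b: "|".join(sorted(b)))).to_csv(
            sep="\t", index=False
        ),
        manifest,
        "rates",
    )
    pts = [
        rates.BranchTrajectoryPoint(r["branch"], r["start_age"], r["end_age"], r["rho"])
        for _, r in ne_df.iterrows()
        if np.isfinite(r["rho"])
    ]
    binned = rates.bin_through_time(pts, bin_width=1.0, mode="overlap-weighted")
    _write(outdir / "rho_binned.tsv", binned.to_csv(sep="\t", index=False), manifest, "rates")


def _stage_traits(cfg, seed, outdir, manifest, state):
    p = cfg["traits"]
    tree = state["model"].tree
    df = traits.simulate_bm_many(
        tree, p["sigma2"], p["n_traits"], lam=p["lambda"], seed=seed
    )
    est = traits.PagelLambdaEstimator(tree)
    fits = [est.fit(df.iloc[:, i].to_numpy()) for i in range(df.shape[1])]
    fit_df = pd.DataFrame(
        {
            "trait": df.columns,
            "lambda": [f.lambda_ for f in fits],
            "sigma2": [f.sigma2 for f in fits],
            "loglik": [f.loglik for f in fits],
        }
    )
    _write(outdir / "trait_lambda.tsv", fit_df.to_csv(sep="\t", index=False), manifest, "traits")
    trait0 = dict(zip(df.index, df.iloc[:, 0]))
    _, binned = traits.ancestral_bm_trajectory(tree, trait0)
    _write(outdir / "trait_trajectory.tsv", binned.to_csv(sep="\t", index=False), manifest, "traits")
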