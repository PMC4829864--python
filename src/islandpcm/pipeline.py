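"""End-to-end orchestration of the island-effect workflow.

Given a tree set (one or many Newick trees), a trait table, group labels,
and either tip island states (for stochastic mapping) or ready-made regime
paintings, :func:`run_pipeline` runs the requested stages per tree --
stochastic mapping, size-correction residuals, phylogenetic ANOVA / MANOVA,
disparity-ratio and pseudo-community tests, BM1/BMS/OU1 fits with AICc
comparison, the BMS parametric bootstrap, and the contrasts-through-time
envelope -- and aggregates results over trees as min / median / mean / max
distributions.

Every source of randomness derives from the master seed through a stable
stage-keyed hash, so adding or removing an analysis does not shift the
random streams of the others, and rerunning a config reproduces the report
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__, disparity, hypotests, mkmap, pcm, treeio

__all__ = ["RunConfig", "RunReport", "run_pipeline", "aggregate_over_trees", "subseed"]

ALL_ANALYSES = (
    "simmap",
    "residuals",
    "anova",
    "manova",
    "disparity",
    "pseudocom",
    "fit",
    "bootstrap",
    "ctt",
)

# stages that cannot run when one of their inputs failed upstream
DEPENDENCIES = {
    "manova": ("residuals",),
    "fit": ("simmap",),
    "bootstrap": ("simmap",),
}

ISLAND_GROUPS = ("Socotra", "AbdAlKuri")
CONTINENT_GROUP = "continent"


def subseed(seed: int, stage: str, index: int = 0) -> int:
    """Stage-keyed 31-bit sub-seed derived from the master seed."""
    h = hashlib.blake2b(f"{seed}:{stage}:{index}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    tree_path: str
    traits_path: str
    groups_path: str
    seed: int
    tip_states_path: str | None = None
    painting_path: str | None = None
    analyses: tuple[str, ...] = ALL_ANALYSES
    n_sims: int = 10_000
    n_maps: int = 100
    n_boot: int = 1000
    n_fit_maps: int = 10
    traits_are_log10: bool = False  # True: CSV already log10; False: raw, transform
    pseudocom_sizes: tuple[int, ...] = (2, 5)
    out_dir: str | None = None

    def validate(self) -> None:
        unknown = [a for a in self.analyses if a not in ALL_ANALYSES]
        if unknown:
            raise ValueError(f"unknown analyses: {unknown}")
        for name in ("n_sims", "n_boot"):
            if getattr(self, name) < 99 and any(
                a in self.analyses for a in ("anova", "manova", "disparity", "bootstrap", "ctt")
            ):
                raise ValueError(f"{name} must be >= 99")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("analyses", "pseudocom_sizes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    config: dict
    version: str
    per_tree: list[dict]
    aggregate: dict
    errors: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=_jsonify)

    @property
    def ok(self) -> bool:
        return not self.errors


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _log(stage: str, event: str, **fields) -> None:
    parts = [f"stage={stage}", f"event={event}"]
    parts += [f"{k}={v}" for k, v in fields.items()]
    print(" ".join(parts), file=sys.stderr)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the configured analyses on every tree in the tree file."""
    config.validate()
    with open(config.tree_path) as fh:
        trees = treeio.read_newick_list(fh.read())
    traits = pcm.TraitTable.read_csv(
        config.traits_path, log10=not config.traits_are_log10
    )
    groups_df = pd.read_csv(config.groups_path)
    cols = {c.lower(): c for c in groups_df.columns}
    groups_all = groups_df.set_index(cols["species"])[cols["group"]]
    tip_states = (
        mkmap.read_tip_states(config.tip_states_path)
        if config.tip_states_path
        else None
    )
    painting_text = None
    if config.painting_path:
        with open(config.painting_path) as fh:
            painting_text = fh.read()

    per_tree: list[dict] = []
    errors: list[dict] = []
    for ti, tree in enumerate(trees):
        _log("pipeline", "tree_start", tree=ti, tips=tree.n_tips)
        res, errs = _run_one_tree(
            config, tree, ti, traits, groups_all, tip_states, painting_text
        )
        per_tree.append(res)
        errors.extend(errs)
    aggregate = aggregate_over_trees(per_tree) if per_tree else {}
    report = RunReport(
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        version=__version__,
        per_tree=per_tree,
        aggregate=aggregate,
        errors=errors,
    )
    if config.out_dir:
        import os

        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report


def _run_one_tree(config, tree, ti, traits, groups_all, tip_states, painting_text):
    results: dict = {"tree_index": ti}
    errors: list[dict] = []
    failed: set[str] = set()
    analyses = list(config.analyses)

    def want(stage):
        if stage not in analyses:
            return False
        missing = [d for d in DEPENDENCIES.get(stage, ()) if d in failed]
        if missing:
            _log(stage, "skipped", tree=ti, reason=f"upstream failure in {missing}")
            errors.append({"tree": ti, "stage": stage, "error": f"skipped: upstream {missing} failed"})
            return False
        return True

    def run(stage, fn):
        try:
            results[stage] = fn()
            _log(stage, "done", tree=ti)
        except Exception as exc:  # pipeline stages fail independently
            failed.add(stage)
            errors.append({"tree": ti, "stage": stage, "error": str(exc)})
            _log(stage, "error", tree=ti, error=type(exc).__name__)

    svl = traits.column("svl")
    groups = groups_all.loc[[s for s in tree.tip_labels if s in groups_all.index]]
    islands = [g for g in ISLAND_GROUPS if g in set(groups)]

    paintings: list = []
    needs_painting = any(a in analyses for a in ("simmap", "fit", "bootstrap"))
    if painting_text is not None and needs_painting:
        try:
            alphabet = sorted(set(groups))
            ptree, painting = treeio.read_painting(painting_text, alphabet)
            painting.validate(tree)  # painting must match this tree's branches
            paintings = [painting]
            results["simmap"] = {"source": "painting_file", "n_maps": 1}
        except Exception as exc:
            failed.add("simmap")
            errors.append({"tree": ti, "stage": "simmap", "error": str(exc)})
    elif want("simmap") and tip_states is not None:

        def do_simmap():
            model = mkmap.fit_mk(tree, tip_states.loc[tree.tip_labels], model="ARD")
            maps = mkmap.stochastic_map(
                tree,
                tip_states.loc[tree.tip_labels],
                model.Q,
                n_maps=config.n_maps,
                seed=subseed(config.seed, "simmap", ti),
                states=model.states,
                root_prior=model.root_prior,
            )
            paintings.extend(maps)
            summary = mkmap.transition_summary(maps)
            return {
                "Q": model.Q.tolist(),
                "states": list(model.states),
                "logL": model.logL,
                "mean_transition_counts": summary["mean_transition_counts"].to_dict(),
                "mean_dwell_times": summary["mean_dwell_times"],
                "n_maps": len(maps),
            }

        run("simmap", do_simmap)
    elif "simmap" in analyses:
        failed.add("simmap")
        errors.append({"tree": ti, "stage": "simmap",
                       "error": "no tip states or painting supplied"})

    head_res: pd.DataFrame | None = None
    if want("residuals"):

        def do_residuals():
            nonlocal head_res
            head_res = pcm.head_residuals(tree, traits)
            return {"traits": list(head_res.columns), "n_species": len(head_res)}

        run("residuals", do_residuals)
        if head_res is None:
            failed.add("residuals")

    if want("anova"):
        run(
            "anova",
            lambda: hypotests.phylo_anova(
                tree, svl, groups, n_sims=config.n_sims,
                seed=subseed(config.seed, "anova", ti),
            ).to_dict(),
        )

    if want("manova") and head_res is not None:
        run(
            "manova",
            lambda: hypotests.phylo_manova(
                tree, head_res, groups, n_sims=config.n_sims,
                seed=subseed(config.seed, "manova", ti),
            ).to_dict(),
        )

    if want("disparity"):

        def do_disparity():
            out = {}
            continent = [s for s in tree.tip_labels if groups.get(s) == CONTINENT_GROUP]
            for island in islands:
                members = [s for s in tree.tip_labels if groups.get(s) == island]
                if len(members) < 2:
                    continue
                out[f"svl_{island}"] = disparity.disparity_ratio_test(
                    tree, svl, members, continent, n_sims=config.n_sims,
                    seed=subseed(config.seed, f"disparity:svl:{island}", ti),
                    mode="univariate",
                ).to_dict()
                if head_res is not None:
                    out[f"head_{island}"] = disparity.disparity_ratio_test(
                        tree, head_res, members, continent, n_sims=config.n_sims,
                        seed=subseed(config.seed, f"disparity:head:{island}", ti),
                        mode="multivariate",
                    ).to_dict()
            return out

        run("disparity", do_disparity)

    if want("pseudocom"):

        def do_pseudocom():
            out = {}
            cont_species = [s for s in groups.index if groups[s] == CONTINENT_GROUP]
            for island in islands:
                isl_species = [s for s in groups.index if groups[s] == island]
                if len(isl_species) < 2:
                    continue
                sub = traits.data.loc[:, ["svl"]]
                out[island] = disparity.pseudo_community_test(
                    sub.loc[cont_species],
                    sub.loc[isl_species],
                    k=len(isl_species),
                    n_resamples=config.n_sims,
                    seed=subseed(config.seed, f"pseudocom:{island}", ti),
                ).to_dict()
            return out

        run("pseudocom", do_pseudocom)

    if want("fit") and paintings:

        def do_fit():
            rows = []
            use = paintings[: config.n_fit_maps]
            for mi, painting in enumerate(use):
                fits = [
                    pcm.fit_bm1(tree, svl),
                    pcm.fit_bms(tree, painting, svl),
                    pcm.fit_ou1(tree, svl),
                ]
                table = pcm.compare_models(fits)
                rows.append(
                    {
                        "map_index": mi,
                        "best": table["model"].iloc[0],
                        "aicc": dict(zip(table["model"], table["aicc"])),
                        "bms_rates": fits[1].sigma2_by_regime,
                    }
                )
            aicc_means = {
                m: float(np.mean([r["aicc"][m] for r in rows]))
                for m in rows[0]["aicc"]
            }
            best_counts = pd.Series([r["best"] for r in rows]).value_counts().to_dict()
            return {"per_map": rows, "aicc_means": aicc_means, "best_counts": best_counts}

        run("fit", do_fit)
    elif "fit" in analyses and not paintings:
        if "fit" not in [e["stage"] for e in errors]:
            errors.append({"tree": ti, "stage": "fit", "error": "no painting available"})

    if want("bootstrap") and paintings:
        run(
            "bootstrap",
            lambda: hypotests.parametric_bootstrap_bms(
                tree, paintings[0], svl, n_boot=config.n_boot,
                seed=subseed(config.seed, "bootstrap", ti),
            ).to_dict(),
        )
    elif "bootstrap" in analyses and not paintings:
        errors.append({"tree": ti, "stage": "bootstrap", "error": "no painting available"})

    if want("ctt"):

        def do_ctt():
            df = disparity.contrasts_through_time(
                tree, svl, n_sims=config.n_sims,
                seed=subseed(config.seed, "ctt", ti),
            )
            return {
                "n_flagged": int(df["flagged"].sum()),
                "n_contrasts": len(df),
                "table": df.to_dict(orient="list"),
            }

        run("ctt", do_ctt)

    return results, errors


# ---------------------------------------------------------------------------
# Aggregation over trees
# ---------------------------------------------------------------------------


def _numeric_leaves(d, prefix=""):
    out = {}
    if isinstance(d, dict):
        for k, v in d.items():
            out.update(_numeric_leaves(v, f"{prefix}{k}." if prefix or True else k))
    elif isinstance(d, bool):
        pass
    elif isinstance(d, (int, float, np.floating, np.integer)):
        out[prefix[:-1]] = float(d)
    return out


def aggregate_over_trees(per_tree: list[dict]) -> dict:
    """Min / max / median / mean of every shared numeric leaf across trees.

    Raises when the trees' result schemas are not identical.
    """
    if not per_tree:
        raise ValueError("no per-tree results to aggregate")
    leaf_maps = []
    for res in per_tree:
        body = {k: v for k, v in res.items() if k != "tree_index"}
        leaf_maps.append(_numeric_leaves(body))
    keys = set(leaf_maps[0])
    for lm in leaf_maps[1:]:
        if set(lm) != keys:
            raise ValueError("heterogeneous result schemas across trees")
    # per-map / per-node detail is reported per tree but not aggregated
    skip = ("per_map", ".table.", ".null.")
    out = {}
    for key in sorted(keys):
        if any(s in key for s in skip):
            continue
        vals = np.array([lm[key] for lm in leaf_maps], dtype=float)
        out[key] = {
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "median": float(np.median(vals)),
            "mean": float(np.mean(vals)),
        }
    return out
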