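"""End-to-end orchestration of the landmark-to-convergence analysis.

Stage order: GPA -> subset extraction -> ordination -> phylogenetic
signal / PGLS -> ecology screens -> prey-size CVA -> UPGMA candidate
selection -> dual convergence tests -> FDR adjustment -> maximal
convergence call.  Every stage draws its randomness from a seed spawned
deterministically from the single run seed, so re-running a config
reproduces all outputs bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import convmorph
from convmorph.comparative import adjust_pgls_table, k_mult, pgls_fit
from convmorph.convergence import (
    DATASETS,
    c_significance_many,
    maximal_convergence_call,
    theta_convergence,
    theta_tables,
    upgma_candidates,
)
from convmorph.landmarks import gpa_align, read_landmarks, species_mean_shapes, subset_shapes
from convmorph.phylo import read_newick
from convmorph.prey_size import PREY_RATIO_CUT, build_ecology, cva_discriminate, pc_ecology_screen
from convmorph.shape_space import pca, select_pcs, scores_table


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    """Declarative run configuration; every printed constant is an option."""

    landmarks: str | None = None
    tree: str | None = None
    ecology: str | None = None
    subset_map: str | None = None
    landmark_format: str = "tps"
    focal_species: str | None = None
    seed: int = 0
    outdir: str | None = None
    pc_variance_pct: float = 1.0  # ">1% of shape variance" PC selection
    pc_screen_pct: float = 5.0  # ">5% of variation" screen selection
    prey_ratio_cut: float = PREY_RATIO_CUT
    alpha: float = 0.10
    n_perm: int = 1000
    n_sims: int = 1000
    n_shuffles: int = 1000
    bh_family: str = "dataset_method"
    realign_subsets: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat = {}
        for key, val in data.items():
            if key in ("thresholds", "counts", "paths") and isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        unknown = set(flat) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self, require_paths: bool = True) -> None:
        if not (0 < self.pc_variance_pct < 100 and 0 < self.pc_screen_pct < 100):
            raise ConfigError("PC variance thresholds must lie in (0, 100)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.prey_ratio_cut:
            raise ConfigError("prey_ratio_cut must be positive")
        if min(self.n_perm, self.n_shuffles) < 1 or self.n_sims < 100:
            raise ConfigError("n_perm/n_shuffles >= 1 and n_sims >= 100 required")
        if self.focal_species is None:
            raise ConfigError("focal_species is required")
        if require_paths:
            for key in ("landmarks", "tree", "ecology"):
                val = getattr(self, key)
                if val is None:
                    raise ConfigError(f"missing required path: {key}")
                if not Path(val).exists():
                    raise ConfigError(f"{key} file not found: {val}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    aligned: dict
    spaces_specimen: dict
    spaces_species: dict
    signal_table: pd.DataFrame
    screen_table: pd.DataFrame
    cva_report: pd.DataFrame
    cva_results: dict
    candidates: object
    convergence_results: pd.DataFrame
    calls: pd.DataFrame
    ecology: pd.DataFrame
    stage_seeds: dict
    output_paths: dict = field(default_factory=dict)


# PGLS model grid: (label, response, predictor, exclude focal?)
_PGLS_MODELS = [
    ("Pcoords ~ ln(Csize)", "shape", "ln_csize", False),
    ("Pcoords ~ clade", "shape", "clade", False),
    ("Pcoords ~ prey/predator mass ratio", "shape", "ln_prey_ratio", True),
    ("Pcoords ~ dietary category (coarse)", "shape", "diet_coarse", True),
    ("Pcoords ~ dietary category (fine)", "shape", "diet_fine", True),
    ("ln(Csize) ~ clade", "size", "clade", False),
    ("ln(Csize) ~ prey/predator mass ratio", "size", "ln_prey_ratio", True),
    ("ln(Csize) ~ dietary category (coarse)", "size", "diet_coarse", True),
    ("ln(Csize) ~ dietary category (fine)", "size", "diet_fine", True),
]


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: PipelineConfig, study=None) -> PipelineResult:
    """Execute the full analysis; ``study`` (a SyntheticStudy) bypasses file input."""
    config.validate(require_paths=study is None)
    master = np.random.SeedSequence(config.seed)
    stage_ss = dict(
        zip(
            ("kmult", "pgls", "csig", "theta"),
            master.spawn(4),
        )
    )
    stage_seeds = {k: _stage_seed(v) for k, v in stage_ss.items()}

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # ---- inputs
    try:
        if study is not None:
            configs, tree, eco_raw = study.configs, study.tree, study.ecology
        else:
            configs = read_landmarks(
                config.landmarks, format=config.landmark_format, subset_map=config.subset_map
            )
            tree = read_newick(config.tree)
            eco_raw = pd.read_csv(config.ecology)
        ecology = build_ecology(eco_raw, prey_ratio_cut=config.prey_ratio_cut)
        ecology = ecology.set_index("species", drop=False)
    except (OSError, ValueError) as err:
        fail("inputs", err)
    focal = config.focal_species
    data_species = sorted({c.species_id for c in configs})
    unknown_eco = [s for s in ecology.index if s not in set(tree.tip_labels)]
    if unknown_eco:
        fail("inputs", ValueError(f"ecology lists species not in the tree: {unknown_eco}"))
    missing_eco = [s for s in data_species if s != focal and s not in set(ecology.index)]
    if missing_eco:
        fail("inputs", ValueError(f"species without ecology records: {missing_eco}"))
    if focal not in set(data_species):
        fail("inputs", ValueError(f"focal species {focal!r} has no specimens"))

    # ---- GPA and subsets
    try:
        total = gpa_align(configs)
        aligned = {"total": total}
        for name in ("facial", "neurocranial"):
            aligned[name] = subset_shapes(total, name, realign=config.realign_subsets)
    except Exception as err:
        fail("gpa", err)

    # ---- ordination
    spaces_specimen, spaces_species, species_order, mean_flat = {}, {}, {}, {}
    try:
        for name, al in aligned.items():
            spaces_specimen[name] = pca(al, level="specimen")
            spaces_species[name] = pca(al, level="species_mean", tree=tree)
            order, means = species_mean_shapes(al, tree=tree)
            species_order[name] = order
            mean_flat[name] = means.reshape(len(order), -1)
    except Exception as err:
        fail("ordination", err)

    # ---- phylogenetic signal + PGLS
    signal_rows = []
    try:
        for name in DATASETS:
            order = species_order[name]
            x = mean_flat[name]
            ks = k_mult(tree, x, n_perm=config.n_perm, seed=stage_seeds["kmult"])
            signal_rows.append(
                {
                    "dataset": name,
                    "function": "K_mult",
                    "df": "",
                    "R2": np.nan,
                    "F": np.nan,
                    "Z": np.nan,
                    "p": ks.p,
                    "statistic": ks.k_mult,
                }
            )
            al = aligned[name]
            lncs = (
                pd.Series(al.ln_csize, index=al.species_ids)
                .groupby(level=0)
                .mean()
                .reindex(order)
            )
            preds = {
                "ln_csize": lncs,
                "clade": ecology["clade"].reindex(order),
                "ln_prey_ratio": ecology["ln_prey_ratio"].reindex(order),
                "diet_coarse": ecology["diet_coarse"].reindex(order),
                "diet_fine": ecology["diet_fine"].reindex(order),
            }
            for label, resp_kind, pred_key, excl in _PGLS_MODELS:
                response = x if resp_kind == "shape" else lncs.to_numpy()[:, None]
                exclude = (focal,) if excl else ()
                try:
                    res = pgls_fit(
                        tree,
                        response,
                        preds[pred_key],
                        species=order,
                        n_perm=config.n_perm,
                        seed=stage_seeds["pgls"],
                        exclude=exclude,
                    )
                except ValueError as err:
                    warnings.warn(f"{name}: model {label!r} skipped: {err}")
                    continue
                signal_rows.append(
                    {
                        "dataset": name,
                        "function": label,
                        "df": f"{res.df[0]},{res.df[1]}",
                        "R2": res.r2,
                        "F": res.f,
                        "Z": res.z,
                        "p": res.p,
                        "statistic": np.nan,
                    }
                )
        signal_table = pd.DataFrame(signal_rows)
        flags, adj = adjust_pgls_table(signal_table["p"].to_numpy(), config.alpha)
        signal_table["p_adjusted"] = adj
        signal_table["significant"] = flags
    except RuntimeError:
        raise
    except Exception as err:
        fail("comparative", err)

    # ---- per-PC ecology screens (species means, focal excluded)
    try:
        screen_rows = []
        for name in DATASETS:
            space = spaces_species[name]
            axes = select_pcs(space, config.pc_screen_pct)
            df_scores = pd.DataFrame(
                space.scores[:, axes],
                index=space.ids,
                columns=[f"PC{a + 1}" for a in axes],
            ).drop(index=focal, errors="ignore")
            tab = pc_ecology_screen(
                df_scores, ecology["ln_prey_ratio"], ecology["size_class"]
            )
            tab.insert(0, "dataset", name)
            screen_rows.append(tab)
        screen_table = pd.concat(screen_rows, ignore_index=True)
    except Exception as err:
        fail("screens", err)

    # ---- CVA prey-size discrimination (specimen level, focal = unknown)
    cva_results, cva_rows = {}, []
    try:
        for name in DATASETS:
            al = aligned[name]
            space = spaces_specimen[name]
            axes = select_pcs(space, config.pc_variance_pct)
            x = space.scores[:, axes]
            cls = np.array(
                [
                    ecology["size_class"].get(sp, "unknown")
                    for sp in al.species_ids
                ],
                dtype=object,
            )
            unknown = np.array([sp == focal for sp in al.species_ids])
            grp = np.array(
                [ecology["clade"].get(sp, "focal") for sp in al.species_ids],
                dtype=object,
            )
            res = cva_discriminate(x, cls, unknown=unknown, groups=grp)
            cva_results[name] = res
            focal_posterior = (
                res.posteriors[unknown].mean(axis=0) if unknown.any() else None
            )
            row = {
                "dataset": name,
                "n_axes": len(axes),
                "pct_correct": res.pct_correct,
                **{f"pct_correct_{g}": v for g, v in res.pct_correct_by.items()},
            }
            if focal_posterior is not None:
                best = int(np.argmax(focal_posterior))
                row["focal_assignment"] = res.classes[best]
                row["focal_posterior"] = float(focal_posterior[best])
            cva_rows.append(row)
        cva_report = pd.DataFrame(cva_rows)
    except Exception as err:
        fail("cva", err)

    # ---- UPGMA candidates (total dataset species means)
    try:
        space = spaces_species["total"]
        axes = select_pcs(space, config.pc_variance_pct)
        cands = upgma_candidates(space.scores[:, axes], space.ids, focal)
    except Exception as err:
        fail("upgma", err)

    # ---- convergence tests
    try:
        conv_rows = []
        for name in DATASETS:
            space = spaces_species[name]
            axes = select_pcs(space, config.pc_variance_pct)
            scores = space.scores[:, axes]
            order = list(space.ids)
            idx = {s: i for i, s in enumerate(order)}
            tip_values = scores[[idx[t] for t in tree.tip_labels]]
            pairs = [(focal, cand) for cand in cands.candidates]
            sig_all = c_significance_many(
                tree, tip_values, pairs, n_sims=config.n_sims, seed=stage_seeds["csig"]
            )
            tables = theta_tables(tree, tip_values)
            for pair in pairs:
                sig = sig_all[pair]
                cm = sig["observed"]
                th = theta_convergence(
                    tree,
                    tip_values,
                    list(pair),
                    n_shuffles=config.n_shuffles,
                    seed=stage_seeds["theta"],
                    tables=tables,
                )
                conv_rows.append(
                    {
                        "species": pair[1],
                        "dataset": name,
                        "c1": cm.c1,
                        "c2": cm.c2,
                        "c3": cm.c3,
                        "c4": cm.c4,
                        "p_c1": sig["p_c1"],
                        "theta": th["theta"],
                        "theta_time": th["theta_time"],
                        "p_theta": th["p_theta"],
                    }
                )
        convergence_results = pd.DataFrame(conv_rows)
        calls = maximal_convergence_call(
            convergence_results, alpha=config.alpha, family=config.bh_family
        )
    except RuntimeError:
        raise
    except Exception as err:
        fail("convergence", err)

    result = PipelineResult(
        config=config,
        aligned=aligned,
        spaces_specimen=spaces_specimen,
        spaces_species=spaces_species,
        signal_table=signal_table,
        screen_table=screen_table,
        cva_report=cva_report,
        cva_results=cva_results,
        candidates=cands,
        convergence_results=convergence_results,
        calls=calls,
        ecology=ecology.reset_index(drop=True),
        stage_seeds=stage_seeds,
    )
    if config.outdir:
        _write_bundle(result)
    return result


def _write_bundle(result: PipelineResult) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name: str, df: pd.DataFrame):
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = p

    save("signal_pgls.csv", result.signal_table)
    save("pc_screens.csv", result.screen_table)
    save("cva_report.csv", result.cva_report)
    save("convergence_results.csv", result.convergence_results)
    save("convergence_calls.csv", result.calls)
    save("ecology.csv", result.ecology)
    for name, space in result.spaces_species.items():
        save(f"species_scores_{name}.csv", scores_table(space))
    save(
        "candidates.csv",
        pd.DataFrame({"species": result.candidates.cluster}),
    )
    log = {
        "version": convmorph.__version__,
        "seed": result.config.seed,
        "stage_seeds": result.stage_seeds,
        "config": {
            k: v for k, v in asdict(result.config).items() if not isinstance(v, Path)
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    paths["run_log.json"] = out / "run_log.json"
    result.output_paths = paths
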