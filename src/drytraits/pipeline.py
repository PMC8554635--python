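"""End-to-end orchestration: traits -> groups -> alpha/FRI -> beta ->
breakpoint/null -> gradient models and trait trends.

All randomness flows from one master seed split per stage, every exclusion
(e.g. river-dates dropped by the minimum-site rule) is logged, and a
manifest records the configuration, seed, per-stage output checksums and
the completed stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .beta import beta_table, spatial_beta, temporal_beta, upgma
from .breakpoint import redundancy_null, segmented_fit, davies_test
from .community import CommunityData
from .groups import alpha_diversity, fca, fri, select_partition, ward_cluster
from .models import fit_lmm, lrt, trait_trend_tree
from .traits import (TraitDatabase, community_trait_profile, gower_distance,
                     relative_abundances)


class InputValidationError(ValueError):
    """Schema/consistency failures, reported exhaustively."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("input validation failed:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    traits_path: str
    community_path: str
    fi_path: str
    out_dir: str
    n_axes: int = 6
    g_min: int = 2
    g_max: int = 25
    min_sites: int = 4
    n_sim: int = 999
    n_perm: int = 999
    alpha: float = 0.05
    null_mode: str = "uniform"
    seed: int = 0


def read_inputs(traits_path: str | Path, community_path: str | Path,
                fi_path: str | Path) -> tuple[TraitDatabase, CommunityData]:
    """Read and cross-validate the three input tables.

    All violations (taxa absent from the trait table, FI out of [0, 100],
    sites without FI, negative abundances) are collected and reported
    together rather than failing at the first one.
    """
    errors: list[str] = []
    trait_db = None
    try:
        trait_db = dio.read_trait_csv(traits_path)
    except Exception as exc:  # noqa: BLE001 - reported in the error bundle
        errors.append(f"trait table: {exc}")
    try:
        records = pd.read_csv(community_path, dtype={"river": str, "site": str,
                                                     "date": str, "taxon": str})
    except Exception as exc:
        errors.append(f"community table: {exc}")
        records = None
    try:
        fi = pd.read_csv(fi_path, dtype={"river": str, "site": str})
    except Exception as exc:
        errors.append(f"FI table: {exc}")
        fi = None

    if records is not None:
        for col in ("river", "site", "date", "taxon", "abundance"):
            if col not in records.columns:
                errors.append(f"community table: missing column {col!r}")
        if "abundance" in records.columns:
            bad = records[records["abundance"] < 0]
            for i in bad.index:
                errors.append(f"community row {i}: negative abundance")
    if fi is not None:
        for col in ("river", "site", "fi"):
            if col not in fi.columns:
                errors.append(f"FI table: missing column {col!r}")
        if "fi" in fi.columns:
            bad = fi[(fi["fi"] < 0) | (fi["fi"] > 100)]
            for _, row in bad.iterrows():
                errors.append(f"FI table: site {row['site']} has FI={row['fi']} outside [0, 100]")
    if records is not None and fi is not None and "site" in records and "site" in fi:
        orphans = sorted(set(records["site"]) - set(fi["site"]))
        for s in orphans:
            errors.append(f"community site {s} has no FI value")
    if trait_db is not None and records is not None and "taxon" in records:
        missing = sorted(set(records["taxon"]) - set(trait_db.taxa))
        for t in missing:
            errors.append(f"community taxon {t} absent from the trait table")
    if errors:
        raise InputValidationError(errors)
    community = CommunityData(records=records, fi=fi)
    return trait_db, community


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)]


def run_all(cfg: RunConfig, trait_db: TraitDatabase | None = None,
            community: CommunityData | None = None) -> dict:
    """Execute the full analysis and write all stage outputs.

    Inputs may be passed in memory (bypassing the CSV read) or loaded and
    validated from the configured paths.  Any stage failure halts the run;
    the manifest then records the stages completed so far.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "completed_stages": [],
        "outputs": {},
        "exclusions": {},
    }
    seeds = _stage_seeds(cfg.seed)
    bundle: dict = {}

    def finish_stage(name: str, files: dict[str, Path]) -> None:
        for key, path in files.items():
            manifest["outputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        manifest["completed_stages"].append(name)
        dio.write_json(manifest, out / "manifest.json")

    try:
        # ---- inputs ------------------------------------------------------
        if trait_db is None or community is None:
            trait_db, community = read_inputs(cfg.traits_path, cfg.community_path,
                                              cfg.fi_path)
        finish_stage("read_inputs", {})

        # ---- traits ------------------------------------------------------
        rel_site = relative_abundances(community, level="site")
        profiles = community_trait_profile(rel_site, trait_db)
        gower = gower_distance(trait_db)
        profiles.values.to_csv(out / "cwm_profiles.csv")
        finish_stage("traits", {"cwm_profiles": out / "cwm_profiles.csv"})

        # ---- functional groups ------------------------------------------
        fca_res = fca(trait_db, n_axes=cfg.n_axes)
        dendro = ward_cluster(fca_res.taxon_scores)
        grouping = select_partition(dendro, cfg.g_min, min(cfg.g_max, trait_db.n_taxa))
        fca_res.taxon_scores.to_csv(out / "fca_scores.csv")
        grouping.assignment.rename("group").to_csv(out / "groups.csv")
        dio.write_newick(dendro.to_newick(), out / "ward_dendrogram.nwk")
        bundle["fca"] = fca_res
        bundle["grouping"] = grouping
        finish_stage("groups", {
            "fca_scores": out / "fca_scores.csv",
            "groups": out / "groups.csv",
            "ward_dendrogram": out / "ward_dendrogram.nwk",
        })

        # ---- alpha & FRI -------------------------------------------------
        alpha = alpha_diversity(rel_site, grouping)
        site_fi = community.site_fi()
        river_of = community.river_of_site()
        alpha["fi"] = site_fi.loc[alpha.index].to_numpy()
        alpha["river"] = river_of.loc[alpha.index].to_numpy()
        fri_res = fri(rel_site, grouping, river_of)
        alpha["fri"] = fri_res.per_site.loc[alpha.index].to_numpy()
        alpha.to_csv(out / "alpha_fri.csv", index_label="site")
        bundle["alpha"] = alpha
        bundle["fri"] = fri_res
        finish_stage("alpha_fri", {"alpha_fri": out / "alpha_fri.csv"})

        # ---- beta --------------------------------------------------------
        tree = upgma(gower)
        spatial, sp_excl = spatial_beta(community, tree, min_sites=cfg.min_sites)
        temporal, tp_excl = temporal_beta(community, tree)
        beta = pd.concat([beta_table(spatial), beta_table(temporal)], ignore_index=True)
        beta.to_csv(out / "beta.csv", index=False)
        dio.write_newick(tree.to_newick(), out / "upgma_dendrogram.nwk")
        manifest["exclusions"]["spatial_beta"] = sp_excl
        manifest["exclusions"]["temporal_beta"] = tp_excl
        bundle["beta"] = beta
        finish_stage("beta", {
            "beta": out / "beta.csv",
            "upgma_dendrogram": out / "upgma_dendrogram.nwk",
        })

        # ---- breakpoint & null ------------------------------------------
        presence = rel_site.gt(0)
        x = alpha["taxonomic_richness"].to_numpy(dtype=float)
        y = alpha["functional_richness"].to_numpy(dtype=float)
        seg = segmented_fit(x, y)
        ensemble = redundancy_null(presence, grouping, n_sim=cfg.n_sim,
                                   mode=cfg.null_mode, seed=seeds[0])
        breakpoint_out = {
            "davies_p": davies_test(x, y),
            "segmented": {
                "psi": seg.psi, "psi_se": seg.psi_se, "psi_ci95": list(seg.psi_ci95),
                "slope_before": seg.slope_before, "slope_after": seg.slope_after,
                "intercept": seg.intercept, "converged": seg.converged,
            },
            "null": {
                "n_sim": ensemble.n_sim, "mode": ensemble.mode,
                "n_valid": ensemble.n_valid, "observed": ensemble.observed,
                "p_values": ensemble.p_values, "tails": ensemble.tails,
            },
        }
        dio.write_json(breakpoint_out, out / "breakpoint.json")
        ensemble.simulations.to_csv(out / "null_simulations.csv", index=False)
        bundle["segmented"] = seg
        bundle["null"] = ensemble
        finish_stage("breakpoint_null", {
            "breakpoint": out / "breakpoint.json",
            "null_simulations": out / "null_simulations.csv",
        })

        # ---- gradient models --------------------------------------------
        models_out = gradient_model_battery(alpha, beta)
        dio.write_json(models_out, out / "models.json")
        bundle["models"] = models_out
        finish_stage("models", {"models": out / "models.json"})

        # ---- trait trends ------------------------------------------------
        trends = {}
        fi_series = site_fi.loc[profiles.values.index]
        for i, trait in enumerate(trait_db.scheme.traits):
            block = profiles.values[trait]
            tree_t = trait_trend_tree(block, fi_series, trait=trait,
                                      alpha=cfg.alpha, n_perm=cfg.n_perm,
                                      seed=seeds[1] + i)
            trends[trait] = {"root_p": tree_t.root_p,
                             "thresholds": tree_t.root.thresholds(),
                             "tree": tree_t.root.to_dict()}
        dio.write_json(trends, out / "trait_trends.json")
        bundle["trends"] = trends
        finish_stage("trends", {"trait_trends": out / "trait_trends.json"})
    except Exception:
        dio.write_json(manifest, out / "manifest.json")
        raise

    bundle["manifest"] = manifest
    return bundle


def gradient_model_battery(alpha: pd.DataFrame, beta: pd.DataFrame) -> dict:
    """The study's mixed-model battery on alpha, FRI and beta tables.

    * z-richness ~ FI x richness type, random intercepts river and site
      nested in river, with sequential likelihood-ratio tests;
    * raw-scale richness ~ FI per type (decline per 10% FI);
    * FRI ~ FI and FRI ~ taxonomic richness, river intercepts;
    * functional ~ taxonomic spatial beta (redundancy check);
    * each beta component ~ FI with river intercepts.
    """
    from .models import z_transform

    out: dict = {}

    long = pd.concat(
        [
            pd.DataFrame({
                "z": z_transform(alpha[col]),
                "richness_type": name,
                "fi": alpha["fi"],
                "river": alpha["river"],
                "site": alpha.index,
            })
            for col, name in (("taxonomic_richness", "taxonomic"),
                              ("functional_richness", "functional"))
        ],
        ignore_index=True,
    )
    full = fit_lmm(long, "z ~ fi * richness_type", groups="river", nested="site")
    no_inter = fit_lmm(long, "z ~ fi + richness_type", groups="river", nested="site")
    fi_only = fit_lmm(long, "z ~ fi", groups="river", nested="site")
    null = fit_lmm(long, "z ~ 1", groups="river", nested="site")
    chi_i, df_i, p_i = lrt(full, no_inter)
    chi_t, df_t, p_t = lrt(no_inter, fi_only)
    chi_f, df_f, p_f = lrt(fi_only, null)
    out["alpha_model"] = full.summary_dict() | {
        "lrt": {
            "fi": {"chi2": chi_f, "df": df_f, "p": p_f},
            "richness_type": {"chi2": chi_t, "df": df_t, "p": p_t},
            "interaction": {"chi2": chi_i, "df": df_i, "p": p_i},
        }
    }

    for col, name in (("taxonomic_richness", "taxonomic"),
                      ("functional_richness", "functional")):
        m = fit_lmm(alpha.assign(response=alpha[col], site=alpha.index),
                    "response ~ fi", groups="river", nested="site")
        out[f"{name}_decline_per_10fi"] = {
            "slope": float(m.params["fi"]), "per_10_fi": float(-10 * m.params["fi"]),
            "se_per_10_fi": float(10 * m.bse["fi"]),
            "intercept": float(m.params["Intercept"]),
        }

    fri_fi = fit_lmm(alpha, "fri ~ fi", groups="river")
    fri_null = fit_lmm(alpha, "fri ~ 1", groups="river")
    chi, df, p = lrt(fri_fi, fri_null)
    out["fri_vs_fi"] = fri_fi.summary_dict() | {"lrt": {"chi2": chi, "df": df, "p": p}}

    fri_tax = fit_lmm(alpha, "fri ~ taxonomic_richness", groups="river")
    chi, df, p = lrt(fri_tax, fri_null)
    out["fri_vs_taxonomic_richness"] = fri_tax.summary_dict() | {
        "lrt": {"chi2": chi, "df": df, "p": p}
    }

    sp = beta[beta["scope"] == "spatial"]
    if len(sp):
        wide = sp.pivot_table(index="unit", columns="family", values="total")
        wide["river"] = sp.drop_duplicates("unit").set_index("unit")["river"]
        if {"taxonomic", "functional"} <= set(wide.columns) and len(wide) >= 4:
            m = fit_lmm(wide.reset_index(), "functional ~ taxonomic", groups="river")
            n = fit_lmm(wide.reset_index(), "functional ~ 1", groups="river")
            chi, df, p = lrt(m, n)
            out["functional_vs_taxonomic_spatial_beta"] = m.summary_dict() | {
                "lrt": {"chi2": chi, "df": df, "p": p}
            }

    for scope in ("spatial", "temporal"):
        for family in ("taxonomic", "functional"):
            sub = beta[(beta["scope"] == scope) & (beta["family"] == family)]
            if len(sub) < 4 or sub["river"].nunique() < 2:
                continue
            for comp in ("total", "replacement", "richness_difference"):
                m = fit_lmm(sub.assign(response=sub[comp]), "response ~ fi",
                            groups="river")
                n = fit_lmm(sub.assign(response=sub[comp]), "response ~ 1",
                            groups="river")
                chi, df, p = lrt(m, n)
                out[f"{scope}_{family}_{comp}"] = {
                    "intercept": float(m.params["Intercept"]),
                    "slope_fi": float(m.params["fi"]),
                    "se": float(m.bse["fi"]),
                    "river_sd": m.random_sd["river"],
                    "chi2": chi, "df": df, "p": p,
                    "n": int(len(sub)),
                }
    return out
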