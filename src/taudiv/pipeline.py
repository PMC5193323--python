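"""Full study orchestration: tau per dataset, pair selection, divergence
points, decay fits, group contrasts, controls and the q-value battery.

The run is driven by a YAML configuration naming the input files; output
is a set of TSV tables plus one JSON summary, written deterministically
(stable ordering, fixed float formatting) so that identical inputs give
byte-identical reports.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divergence_stats as ds
from . import pairing, specificity
from .errors import ConfigError
from .io_tables import (
    AgeCalibration,
    ExpressionMatrix,
    TissueMap,
    read_calibration,
    read_expression,
    read_gene_list,
    read_homology,
    read_tissue_map,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

#: conditions recomputing tau with one tissue removed
TISSUE_CONDITIONS = {
    "no_testis": "testis",
    "no_brain": "brain",
    "no_heart": "heart",
    "no_kidney": "kidney",
    "no_liver": "liver",
}


@dataclass
class StudyInputs:
    expression: dict  # species -> ExpressionMatrix (linear scale)
    homology: pd.DataFrame
    calibration: AgeCalibration
    tissue_map: TissueMap
    focal_species: str
    threshold: float = 0.8
    threshold_sweep: tuple = (0.3, 0.8)
    conditions: tuple = ("all", "no_testis", "no_brain", "no_heart", "no_kidney", "no_liver")
    testis_label: str = "testis"
    exclude_genes: frozenset = frozenset()
    conserved_intersection: bool = True
    seed: int = 0


@dataclass
class RunReport:
    points: pd.DataFrame  # divergence points, all conditions
    fits: pd.DataFrame  # decay fits + model comparisons per condition/class
    battery: pd.DataFrame  # (test_id, p, q)
    same_tissue: pd.DataFrame
    asymmetry: pd.DataFrame
    summary: dict = field(default_factory=dict)


def load_inputs(config: dict, base_dir) -> StudyInputs:
    """Resolve a parsed YAML study configuration into loaded inputs."""
    base = Path(base_dir)
    expression = {}
    for entry in config["expression"]:
        matrix = read_expression(
            base / entry["path"], entry["species"], entry.get("dataset", entry["species"])
        )
        expression[entry["species"]] = matrix
    focal = config["focal_species"]
    if focal not in expression:
        raise ConfigError(f"focal species {focal!r} has no expression table")
    exclude = frozenset()
    if config.get("exclude_genes"):
        exclude = read_gene_list(base / config["exclude_genes"])
    return StudyInputs(
        expression=expression,
        homology=read_homology(base / config["homology"]),
        calibration=read_calibration(base / config["calibration"]),
        tissue_map=read_tissue_map(base / config["tissue_map"]),
        focal_species=focal,
        threshold=float(config.get("threshold", 0.8)),
        threshold_sweep=tuple(config.get("threshold_sweep", (0.3, 0.8))),
        conditions=tuple(config.get("conditions", StudyInputs.conditions)),
        testis_label=config.get("testis_label", "testis"),
        exclude_genes=exclude,
        conserved_intersection=bool(config.get("conserved_intersection", True)),
        seed=int(config.get("seed", 0)),
    )


def load_config(path) -> tuple[dict, Path]:
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return config, path.parent


# ---------------------------------------------------------------------------
# Helper stages
# ---------------------------------------------------------------------------


def conserved_ortholog_intersection(pair_tables: dict) -> dict:
    """Restrict each species' ortholog pairs to focal genes shared by all.

    ``pair_tables`` maps species -> AnalysisPair frame whose ``gene_ref``
    is the focal gene.  Species with empty tables are ignored for the
    intersection but returned restricted (empty).
    """
    gene_sets = [set(t["gene_ref"]) for t in pair_tables.values() if len(t)]
    if not gene_sets:
        return {sp: t.copy() for sp, t in pair_tables.items()}
    conserved = set.intersection(*gene_sets)
    if not conserved:
        logger.warning("conserved-ortholog intersection is empty")
    return {
        sp: t[t["gene_ref"].isin(conserved)].reset_index(drop=True)
        for sp, t in pair_tables.items()
    }


def _local_labels(tissue_map: TissueMap, species: str, canonical: str) -> set:
    return {loc for (sp, loc), can in tissue_map.items() if sp == species and can == canonical}


def _tau_tables(
    inputs: StudyInputs, excluded_canonical: str | None
) -> dict[str, pd.DataFrame]:
    """Tau per species, optionally with one canonical tissue removed.

    The exclusion is translated to each species' local labels via the
    tissue map; species lacking the tissue keep their full panel.
    """
    tables = {}
    for species, matrix in inputs.expression.items():
        excluded: set = set()
        if excluded_canonical:
            excluded = _local_labels(inputs.tissue_map, species, excluded_canonical)
            excluded &= set(matrix.tissues)
        tables[species] = specificity.build_tau_table(
            matrix, threshold=inputs.threshold, excluded_tissues=excluded
        )
    return tables


def _drop_excluded_genes(pairs: pd.DataFrame, exclude: frozenset) -> pd.DataFrame:
    if not exclude or pairs.empty:
        return pairs
    keep = ~(pairs["gene_ref"].isin(exclude) | pairs["gene_alt"].isin(exclude))
    return pairs[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Main run
# ---------------------------------------------------------------------------


def run_study(inputs: StudyInputs) -> RunReport:
    """Execute the full comparative analysis on loaded inputs."""
    focal = inputs.focal_species
    others = sorted(sp for sp in inputs.expression if sp != focal)

    condition_tissue = {"all": None}
    for cond in inputs.conditions:
        if cond == "all":
            continue
        if cond not in TISSUE_CONDITIONS:
            raise ConfigError(f"unknown condition {cond!r}")
        condition_tissue[cond] = TISSUE_CONDITIONS[cond]

    # pair selection does not depend on the tissue condition; tau tables do
    base_tau = _tau_tables(inputs, None)
    ortho_pairs = {
        sp: pairing.select_ortholog_pairs(inputs.homology, focal, sp, inputs.calibration)
        for sp in others
    }
    paralog_pairs = pairing.select_youngest_paralog_pairs(
        inputs.homology, focal, inputs.calibration, base_tau[focal]
    )
    triplets = pairing.attach_outgroups(paralog_pairs, inputs.homology, inputs.calibration)

    battery: list[tuple[str, float]] = []
    all_points: list[ds.DivergencePoint] = []
    fit_rows: list[dict] = []
    same_rows: list[pd.DataFrame] = []
    asym_frames: list[pd.DataFrame] = []
    condition_points: dict[str, dict[str, list]] = {}

    def decay_and_record(points, cls, condition):
        if len(points) < 4 or len({p.age_my for p in points}) < 2:
            return None
        fit = ds.fit_decay(points)
        for model in ("linear", "log10"):
            f: ds.DecayFit = fit[model]
            fit_rows.append(
                {
                    "condition": condition, "pair_class": cls, "record": f"fit_{model}",
                    "slope": f.slope, "intercept": f.intercept,
                    "slope_p": f.slope_p, "rss": f.rss,
                    "f_stat": np.nan, "p_value": np.nan, "preferred": "",
                }
            )
        cmp_: ds.ModelComparison = fit["comparison"]
        fit_rows.append(
            {
                "condition": condition, "pair_class": cls, "record": "linear_vs_log10",
                "slope": np.nan, "intercept": np.nan, "slope_p": np.nan, "rss": np.nan,
                "f_stat": cmp_.f_stat, "p_value": cmp_.p_value, "preferred": cmp_.preferred,
            }
        )
        if np.isfinite(cmp_.p_value):
            battery.append((f"{condition}:{cls}:linear_vs_log10", cmp_.p_value))
        return fit

    def group_and_record(pts_a, pts_b, label_a, label_b, condition, record):
        if not pts_a or not pts_b or len(pts_a) + len(pts_b) < 4:
            return None
        cmp_ = ds.compare_groups(pts_a, pts_b, label_a, label_b)
        fit_rows.append(
            {
                "condition": condition, "pair_class": f"{label_a}_vs_{label_b}",
                "record": record, "slope": np.nan, "intercept": np.nan,
                "slope_p": np.nan, "rss": np.nan,
                "f_stat": cmp_.f_stat, "p_value": cmp_.p_value, "preferred": cmp_.preferred,
            }
        )
        battery.append((f"{condition}:{record}", cmp_.p_value))
        return cmp_

    for condition, excl_tissue in condition_tissue.items():
        tau = base_tau if excl_tissue is None else _tau_tables(inputs, excl_tissue)
        opoints, ppoints = [], []
        for sp in others:
            point = ds.tau_correlation(
                ortho_pairs[sp], tau[focal], tau[sp],
                dataset_id=inputs.expression[sp].dataset_id, condition=condition,
            )
            if point is not None:
                opoints.append(point)
        if not paralog_pairs.empty:
            for (node, age), grp in paralog_pairs.groupby(["node_label", "age_my"], sort=True):
                point = ds.tau_correlation(
                    grp, tau[focal], tau[focal],
                    dataset_id=inputs.expression[focal].dataset_id, condition=condition,
                )
                if point is not None:
                    ppoints.append(point)
        all_points.extend(opoints + ppoints)
        condition_points[condition] = {"ortholog": opoints, "paralog": ppoints}

        decay_and_record(opoints, "ortholog", condition)
        decay_and_record(ppoints, "paralog", condition)
        group_and_record(
            opoints, ppoints, "ortholog", "paralog", condition, "ortholog_vs_paralog"
        )
        if condition != "all":
            base = condition_points["all"]
            group_and_record(
                base["ortholog"], opoints, "all", condition, condition,
                "ortholog_condition_effect",
            )
            group_and_record(
                base["paralog"], ppoints, "all", condition, condition,
                "paralog_condition_effect",
            )

        # asymmetry against the unduplicated outgroup
        if not triplets.empty:
            asym = ds.outgroup_asymmetry(triplets, tau[focal], tau, condition=condition)
            if len(asym):
                asym_frames.append(asym)

        # same-tissue contingency over the threshold sweep
        for thr in inputs.threshold_sweep:
            for sp in others:
                counts = ds.same_tissue_counts(
                    ortho_pairs[sp], tau[focal], tau[sp], inputs.tissue_map,
                    species_ref=focal, species_alt=sp, threshold=thr,
                )
                if len(counts):
                    counts.insert(0, "condition", condition)
                    counts.insert(1, "threshold", thr)
                    counts.insert(2, "species_alt", sp)
                    same_rows.append(counts)
            if not paralog_pairs.empty:
                counts = ds.same_tissue_counts(
                    paralog_pairs, tau[focal], tau[focal], inputs.tissue_map,
                    species_ref=focal, species_alt=focal, threshold=thr,
                )
                if len(counts):
                    counts.insert(0, "condition", condition)
                    counts.insert(1, "threshold", thr)
                    counts.insert(2, "species_alt", focal)
                    same_rows.append(counts)

    # gene-exclusion control (e.g. sex-chromosome genes)
    if inputs.exclude_genes:
        opoints = []
        for sp in others:
            restricted = _drop_excluded_genes(ortho_pairs[sp], inputs.exclude_genes)
            point = ds.tau_correlation(
                restricted, base_tau[focal], base_tau[sp],
                dataset_id=inputs.expression[sp].dataset_id, condition="gene_exclusion",
            )
            if point is not None:
                opoints.append(point)
        rpp = _drop_excluded_genes(paralog_pairs, inputs.exclude_genes)
        ppoints = []
        if not rpp.empty:
            for (node, age), grp in rpp.groupby(["node_label", "age_my"], sort=True):
                point = ds.tau_correlation(
                    grp, base_tau[focal], base_tau[focal],
                    dataset_id=inputs.expression[focal].dataset_id,
                    condition="gene_exclusion",
                )
                if point is not None:
                    ppoints.append(point)
        all_points.extend(opoints + ppoints)
        group_and_record(
            condition_points["all"]["ortholog"], opoints, "all", "gene_exclusion",
            "gene_exclusion", "ortholog_condition_effect",
        )
        group_and_record(
            condition_points["all"]["paralog"], ppoints, "all", "gene_exclusion",
            "gene_exclusion", "paralog_condition_effect",
        )

    # conserved-ortholog intersection control
    if inputs.conserved_intersection and len(others) >= 2:
        restricted = conserved_ortholog_intersection(ortho_pairs)
        opoints = []
        for sp in others:
            point = ds.tau_correlation(
                restricted[sp], base_tau[focal], base_tau[sp],
                dataset_id=inputs.expression[sp].dataset_id,
                condition="conserved_orthologs",
            )
            if point is not None:
                opoints.append(point)
        all_points.extend(opoints)
        n_conserved = len(set().union(*[set(t["gene_ref"]) for t in restricted.values()])) \
            if any(len(t) for t in restricted.values()) else 0
        group_and_record(
            condition_points["all"]["ortholog"], opoints, "all", "conserved",
            "conserved_orthologs", "ortholog_condition_effect",
        )
    else:
        n_conserved = None

    # q-values over the realized battery
    battery_df = pd.DataFrame(battery, columns=["test_id", "p"])
    if len(battery_df):
        battery_df["q"] = ds.qvalues(battery_df["p"].to_numpy())
    else:
        battery_df["q"] = []

    points_df = ds.points_frame(all_points) if all_points else pd.DataFrame(
        columns=["age_my", "r", "n_pairs", "pair_class", "dataset_id", "condition", "node_label"]
    )
    points_df = points_df.sort_values(
        ["condition", "pair_class", "age_my", "dataset_id"], kind="stable"
    ).reset_index(drop=True)
    fits_df = pd.DataFrame(fit_rows)
    same_df = (
        pd.concat(same_rows, ignore_index=True)
        if same_rows
        else pd.DataFrame(
            columns=["condition", "threshold", "species_alt", "node_label", "age_my",
                     "pair_class", "n_same", "n_different", "n_excluded"]
        )
    )
    same_df = same_df.sort_values(
        ["condition", "threshold", "species_alt", "age_my", "pair_class"], kind="stable"
    ).reset_index(drop=True)
    asym_df = (
        pd.concat(asym_frames, ignore_index=True)
        if asym_frames
        else pd.DataFrame(columns=["node_label", "age_my", "role", "r", "n", "condition"])
    )

    summary = {
        "focal_species": focal,
        "n_ortholog_points": int((points_df["pair_class"] == "ortholog").sum()),
        "n_paralog_points": int((points_df["pair_class"] == "paralog").sum()),
        "n_paralog_pairs": int(len(paralog_pairs)),
        "n_outgroup_triplets": int(len(triplets)),
        "n_tests": int(len(battery_df)),
        "paralog_sections_present": not paralog_pairs.empty,
        "n_conserved_orthologs": n_conserved,
        "seed": inputs.seed,
    }
    return RunReport(points_df, fits_df, battery_df, same_df, asym_df, summary)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------


def write_report(report: RunReport, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "points.tsv": report.points,
        "fits.tsv": report.fits,
        "battery.tsv": report.battery,
        "same_tissue.tsv": report.same_tissue,
        "asymmetry.tsv": report.asymmetry,
    }
    hashes = {}
    for name, df in tables.items():
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    summary = dict(report.summary)
    summary["table_sha256"] = hashes
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("write_report: report written to %s", out_dir)
    return out_dir


def run_study_from_config(config_path, out_dir=None) -> RunReport:
    config, base = load_config(config_path)
    inputs = load_inputs(config, base)
    report = run_study(inputs)
    if out_dir is not None:
        write_report(report, out_dir)
    return report
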