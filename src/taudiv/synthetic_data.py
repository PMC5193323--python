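"""Synthetic expression-evolution generator with known ground truth.

The generator emulates the statistical structure a multi-species tissue
panel shows: a broad bimodal distribution of tissue-specificity (a large
ubiquitous class and a large specific class, enriched for testis), tau
conserved between orthologs with correlation decaying with divergence
time, paralog pairs that decorrelate immediately upon duplication through
asymmetric loss of expression in the minor copy, and gradual broadening of
paralog expression with age.

Model.  Each ancestral gene has a linear expression profile ``scale *
shares`` over tissues; shares come from a two-component Dirichlet mixture
(low concentration -> tissue-specific, high concentration -> ubiquitous).
Expression evolves by Brownian drift in log2 space along a caterpillar
species tree (the focal lineage plus one branch per comparison species),
with per-tissue increments of standard deviation sigma_e * sqrt(t) over a
branch of t My.  A duplication at age ``a`` splits the focal-lineage state
into two copies: dosage sharing gives the major copy a fraction
``major_share`` of the linear level, the minor copy loses a fraction
``asym_loss`` of its expression in non-peak tissues (or, for the ohnolog
scenario, re-specifies to another tissue with probability
``respecify_prob``), after which both copies drift for ``a`` My while
non-peak tissues additionally rise at ``broadening_rate`` log2 units per
My.  Tip log2 values are floored at 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_tables import (
    AgeCalibration,
    ExpressionMatrix,
    TissueMap,
    write_calibration,
    write_expression,
    write_homology,
    write_tissue_map,
)
from .specificity import _tau_rows

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("brain", "cerebellum", "heart", "kidney", "liver", "testis")

#: comparison species on the focal (human-like) lineage: name -> (node, My)
DEFAULT_SPLITS = (
    ("chimpanzee", "Homininae", 6.0),
    ("macaque", "Catarrhini", 25.0),
    ("mouse", "Euarchontoglires", 90.0),
    ("opossum", "Theria", 160.0),
    ("chicken", "Amniota", 300.0),
    ("frog", "Tetrapoda", 361.0),
)


@dataclass
class DuplicationScenario:
    """One class of duplication events at a fixed node age."""

    node_label: str
    age_my: float
    n_families: int = 250
    dosage_share: bool = True
    major_share: float = 0.7  # fraction of the ancestral level kept by the major copy
    asym_loss: float = 0.8  # fraction of non-peak expression lost by the minor copy
    broadening_rate: float = 0.002  # log2 units per My added to non-peak tissues
    respecify_prob: float = 0.0  # minor copy moves its peak to another tissue

    def __post_init__(self):
        if self.age_my <= 0:
            raise ConfigError(f"duplication age must be positive, got {self.age_my}")
        if not 0 <= self.asym_loss <= 1:
            raise ConfigError(f"asym_loss must be in [0, 1], got {self.asym_loss}")
        if not 0 < self.major_share < 1:
            raise ConfigError(f"major_share must be in (0, 1), got {self.major_share}")
        if not 0 <= self.respecify_prob <= 1:
            raise ConfigError(f"respecify_prob must be in [0, 1]")
        if self.broadening_rate < 0 or self.n_families < 0:
            raise ConfigError("rates and family counts must be >= 0")


def default_scenarios() -> list[DuplicationScenario]:
    """Small-scale duplication classes plus an old whole-genome-like class."""
    return [
        DuplicationScenario("Primates", 25.0),
        DuplicationScenario("Eutheria", 90.0),
        DuplicationScenario("Theria", 160.0),
        DuplicationScenario("Amniota", 300.0),
        DuplicationScenario("Vertebrata", 500.0, respecify_prob=0.5),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle."""

    n_genes: int = 3000  # single-copy (ortholog) ancestors
    tissues: tuple = DEFAULT_TISSUES
    focal_species: str = "human"
    splits: tuple = DEFAULT_SPLITS
    sigma_e: float = 0.15  # log2 drift sd per sqrt(My)
    frac_specific: float = 0.4  # weight of the tissue-specific ancestor class
    conc_specific: float = 0.1  # Dirichlet concentration of the specific class
    conc_broad: float = 30.0  # Dirichlet concentration of the ubiquitous class
    testis_bias: float = 0.4  # P(peak tissue = testis | specific ancestor)
    log2_scale_mean: float = 6.0  # mean of log2 peak-level distribution
    log2_scale_sd: float = 2.0
    scenarios: list = field(default_factory=default_scenarios)

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.tissues) < 2:
            raise ConfigError("need at least 2 tissues")
        if self.sigma_e < 0:
            raise ConfigError("sigma_e must be >= 0")
        if not 0 <= self.frac_specific <= 1:
            raise ConfigError("frac_specific must be in [0, 1]")
        if self.conc_specific <= 0 or self.conc_broad <= 0:
            raise ConfigError("Dirichlet concentrations must be positive")
        if not 0 <= self.testis_bias <= 1:
            raise ConfigError("testis_bias must be in [0, 1]")
        if "testis" not in self.tissues and self.testis_bias > 0:
            raise ConfigError("testis_bias > 0 requires a 'testis' tissue")

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyBundle:
    """In-memory synthetic study: expression per species plus side tables."""

    expression: dict  # species -> ExpressionMatrix
    homology: pd.DataFrame
    calibration: AgeCalibration
    tissue_map: TissueMap
    truth: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# Ancestors
# ---------------------------------------------------------------------------


def simulate_ancestors(config: SimulationConfig, rng: np.random.Generator, n: int | None = None):
    """Draw ancestral log2 profiles and their ground truth.

    Returns ``(log2_profiles, truth)`` where truth records the mixture
    component, peak tissue and ancestral tau of every gene.
    """
    n = config.n_genes if n is None else n
    T = config.n_tissues
    specific = rng.random(n) < config.frac_specific

    shares = np.empty((n, T))
    n_spec = int(specific.sum())
    if n_spec:
        shares[specific] = rng.dirichlet(np.full(T, config.conc_specific), size=n_spec)
    if n - n_spec:
        shares[~specific] = rng.dirichlet(np.full(T, config.conc_broad), size=n - n_spec)

    # bias the peak of specific genes towards testis by swapping shares
    if config.testis_bias > 0 and n_spec:
        testis_idx = config.tissues.index("testis")
        to_testis = specific & (rng.random(n) < config.testis_bias)
        idx = np.flatnonzero(to_testis)
        cur_max = shares[idx].argmax(axis=1)
        for i, j in zip(idx, cur_max):
            shares[i, [j, testis_idx]] = shares[i, [testis_idx, j]]

    scale = 2.0 ** rng.normal(config.log2_scale_mean, config.log2_scale_sd, size=n)
    linear = scale[:, None] * shares / shares.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        log2 = np.where(linear > 0, np.log2(linear), -50.0)

    anc_tau = _tau_rows(np.clip(log2, 0.0, None))
    truth = pd.DataFrame(
        {
            "component": np.where(specific, "specific", "broad"),
            "peak_tissue": [config.tissues[j] for j in shares.argmax(axis=1)],
            "ancestral_tau": anc_tau,
        }
    )
    return log2, truth


# ---------------------------------------------------------------------------
# Drift and duplication primitives
# ---------------------------------------------------------------------------


def _drift(profiles: np.ndarray, t_my: float, sigma_e: float, rng: np.random.Generator):
    if t_my < 0:
        raise ConfigError("branch length must be >= 0")
    if t_my == 0 or sigma_e == 0:
        return profiles.copy()
    return profiles + rng.normal(0.0, sigma_e * np.sqrt(t_my), size=profiles.shape)


def evolve_orthologs(
    ancestors: np.ndarray, t_my: float, sigma_e: float, rng: np.random.Generator
):
    """Two descendant log2 matrices after independent drift for t My each.

    Tip values are floored at 0 (absence level).
    """
    a = np.clip(_drift(ancestors, t_my, sigma_e, rng), 0.0, None)
    b = np.clip(_drift(ancestors, t_my, sigma_e, rng), 0.0, None)
    return a, b


def duplicate_genes(
    profiles: np.ndarray,
    scenario: DuplicationScenario,
    sigma_e: float,
    rng: np.random.Generator,
):
    """Split ancestral log2 profiles into evolved major/minor copies.

    Returns ``(major, minor, minor_respecified)``: tip log2 matrices
    (floored at 0) and a boolean flag per family marking re-specified
    minor copies.
    """
    major = profiles.copy()
    minor = profiles.copy()
    n, T = profiles.shape
    peak = profiles.argmax(axis=1)
    rows = np.arange(n)

    if scenario.dosage_share:
        major += np.log2(scenario.major_share)
        minor += np.log2(1.0 - scenario.major_share)

    respecified = rng.random(n) < scenario.respecify_prob
    if scenario.respecify_prob > 0:
        # minor copy moves its peak to a uniformly chosen other tissue
        offsets = rng.integers(1, T, size=n)
        new_peak = (peak + offsets) % T
        idx = np.flatnonzero(respecified)
        for i in idx:
            minor[i, [peak[i], new_peak[i]]] = minor[i, [new_peak[i], peak[i]]]
        minor_peak = np.where(respecified, new_peak, peak)
    else:
        minor_peak = peak

    # asymmetric loss: minor copy loses expression outside its peak tissue
    if scenario.asym_loss > 0:
        loss = np.log2(1.0 - scenario.asym_loss) if scenario.asym_loss < 1 else -50.0
        mask = np.ones((n, T), dtype=bool)
        mask[rows, minor_peak] = False
        minor = np.where(mask, minor + loss, minor)

    major = _drift(major, scenario.age_my, sigma_e, rng)
    minor = _drift(minor, scenario.age_my, sigma_e, rng)

    # broadening: non-peak tissues of each copy rise with age
    if scenario.broadening_rate > 0:
        bump = scenario.broadening_rate * scenario.age_my
        maj_mask = np.ones((n, T), dtype=bool)
        maj_mask[rows, peak] = False
        min_mask = np.ones((n, T), dtype=bool)
        min_mask[rows, minor_peak] = False
        major = np.where(maj_mask, major + bump, major)
        minor = np.where(min_mask, minor + bump, minor)

    return np.clip(major, 0.0, None), np.clip(minor, 0.0, None), respecified


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


def _outgroup_for(scenario_age: float, splits) -> tuple[str, str, float] | None:
    """Closest comparison species that split strictly before the duplication."""
    older = [s for s in splits if s[2] > scenario_age]
    return min(older, key=lambda s: s[2]) if older else None


def simulate_study(config: SimulationConfig, seed: int) -> StudyBundle:
    """Generate the full multi-species bundle with ground truth.

    All genes share one Brownian history along the focal lineage, so
    correlations between any two tips are consistent with the species
    tree.  Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    n_family_total = sum(s.n_families for s in config.scenarios)
    n_total = config.n_genes + n_family_total
    ancestors, truth = simulate_ancestors(config, rng, n=n_total)

    single_idx = np.arange(config.n_genes)
    fam_slices: list[tuple[DuplicationScenario, np.ndarray]] = []
    start = config.n_genes
    for scen in config.scenarios:
        fam_slices.append((scen, np.arange(start, start + scen.n_families)))
        start += scen.n_families

    splits = list(config.splits)
    split_ages = {name: age for name, _, age in splits}
    # outgroup species per scenario (None when no species is old enough)
    outgroups = {scen.node_label: _outgroup_for(scen.age_my, splits) for scen, _ in fam_slices}

    breakpoints = sorted(
        {age for _, _, age in splits} | {scen.age_my for scen, _ in fam_slices},
        reverse=True,
    )

    sp = config.focal_species
    gene_id = lambda i, species, suffix="": f"g{i:05d}_{species}{suffix}"

    tips: dict[str, dict[str, np.ndarray]] = {s[0]: {} for s in splits}
    tips[sp] = {}
    hom_rows: list[tuple] = []
    truth_rows: list[dict] = []

    state = ancestors.copy()
    prev_t = breakpoints[0]
    for t in breakpoints:
        if t < prev_t:
            state = _drift(state, prev_t - t, config.sigma_e, rng)
            prev_t = t
        # species splitting at this time: emit tips for single-copy genes
        # and for outgroup genes of families assigned to this species
        for name, node, age in splits:
            if age != t:
                continue
            tip_rows = [single_idx]
            og_fams: list[tuple[DuplicationScenario, np.ndarray]] = []
            for scen, idx in fam_slices:
                og = outgroups[scen.node_label]
                if og is not None and og[0] == name:
                    tip_rows.append(idx)
                    og_fams.append((scen, idx))
            all_idx = np.concatenate(tip_rows)
            evolved = np.clip(
                _drift(state[all_idx], t, config.sigma_e, rng), 0.0, None
            )
            pos = {g: k for k, g in enumerate(all_idx)}
            for i in single_idx:
                tips[name][gene_id(i, name)] = evolved[pos[i]]
                hom_rows.append(
                    (
                        gene_id(i, sp), sp, gene_id(i, name), name,
                        "one2one_ortholog", node, f"fam{i:05d}",
                    )
                )
            for scen, idx in og_fams:
                for i in idx:
                    og_gene = gene_id(i, name)
                    tips[name][og_gene] = evolved[pos[i]]
                    for suffix in ("_p1", "_p2"):
                        hom_rows.append(
                            (
                                gene_id(i, sp, suffix), sp, og_gene, name,
                                "one2two_outgroup", node, f"fam{i:05d}",
                            )
                        )
        # duplications at this time: spawn the two focal-species copies
        for scen, idx in fam_slices:
            if scen.age_my != t:
                continue
            major, minor, respec = duplicate_genes(
                state[idx], scen, config.sigma_e, rng
            )
            for k, i in enumerate(idx):
                g1, g2 = gene_id(i, sp, "_p1"), gene_id(i, sp, "_p2")
                tips[sp][g1] = major[k]
                tips[sp][g2] = minor[k]
                hom_rows.append(
                    (g1, sp, g2, sp, "within_species_paralog", scen.node_label, f"fam{i:05d}")
                )
                truth_rows.append(
                    {
                        "gene_id": g1, "species_id": sp, "role": "major",
                        "family_id": f"fam{i:05d}", "true_age_my": scen.age_my,
                        "node_label": scen.node_label,
                        "respecified": False,
                        "ancestral_tau": truth.loc[i, "ancestral_tau"],
                        "peak_tissue": truth.loc[i, "peak_tissue"],
                    }
                )
                truth_rows.append(
                    {
                        "gene_id": g2, "species_id": sp, "role": "minor",
                        "family_id": f"fam{i:05d}", "true_age_my": scen.age_my,
                        "node_label": scen.node_label,
                        "respecified": bool(respec[k]),
                        "ancestral_tau": truth.loc[i, "ancestral_tau"],
                        "peak_tissue": truth.loc[i, "peak_tissue"],
                    }
                )
    # focal tips for single-copy genes: finish the lineage to the present
    state = _drift(state, prev_t, config.sigma_e, rng)
    focal = np.clip(state, 0.0, None)
    for i in single_idx:
        tips[sp][gene_id(i, sp)] = focal[i]
        truth_rows.append(
            {
                "gene_id": gene_id(i, sp), "species_id": sp, "role": "single",
                "family_id": f"fam{i:05d}", "true_age_my": np.nan,
                "node_label": "", "respecified": False,
                "ancestral_tau": truth.loc[i, "ancestral_tau"],
                "peak_tissue": truth.loc[i, "peak_tissue"],
            }
        )

    tissue_list = list(config.tissues)
    expression = {}
    for species, genes in tips.items():
        names = sorted(genes)
        values = 2.0 ** np.array([genes[g] for g in names])
        df = pd.DataFrame(values, index=names, columns=tissue_list)
        df.index.name = "gene_id"
        expression[species] = ExpressionMatrix(species, f"synth_{species}", df)

    homology = pd.DataFrame(
        hom_rows,
        columns=[
            "gene_a", "species_a", "gene_b", "species_b",
            "relation", "node_label", "family_id",
        ],
    ).sort_values(["relation", "gene_a", "gene_b"], kind="stable").reset_index(drop=True)

    ages = {node: age for _, node, age in splits}
    for scen, _ in fam_slices:
        if scen.node_label in ages and ages[scen.node_label] != scen.age_my:
            raise ConfigError(
                f"node label {scen.node_label!r} used with two different ages"
            )
        ages[scen.node_label] = scen.age_my
    calibration = AgeCalibration(ages)

    tissue_map = TissueMap(
        {
            (species, tissue): tissue
            for species in expression
            for tissue in tissue_list
        }
    )

    truth_df = pd.DataFrame(truth_rows).sort_values("gene_id", kind="stable")
    truth_df = truth_df.set_index("gene_id")

    manifest = {
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "n_genes": int(config.n_genes),
        "n_families": int(n_family_total),
        "species": sorted(expression),
        "focal_species": sp,
    }
    logger.info(
        "simulate_study: %d species, %d single-copy genes, %d families (seed %d)",
        len(expression), config.n_genes, n_family_total, seed,
    )
    return StudyBundle(expression, homology, calibration, tissue_map, truth_df, manifest)


def emit_dataset(config: SimulationConfig, out_dir, seed: int) -> Path:
    """Write a bundle to disk in the formats the readers accept.

    Layout: ``expr_<species>.tsv`` per species, ``homology.tsv``,
    ``calibration.tsv``, ``tissue_map.tsv``, ``truth.tsv`` and
    ``manifest.json``.  On failure the partially written directory is
    removed.  Identical (config, seed) produce byte-identical bundles.
    """
    out_dir = Path(out_dir)
    bundle = simulate_study(config, seed)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        for species, matrix in sorted(bundle.expression.items()):
            write_expression(matrix, out_dir / f"expr_{species}.tsv")
        write_homology(bundle.homology, out_dir / "homology.tsv")
        write_calibration(bundle.calibration, out_dir / "calibration.tsv")
        write_tissue_map(bundle.tissue_map, out_dir / "tissue_map.tsv")
        bundle.truth.to_csv(out_dir / "truth.tsv", sep="\t", float_format="%.6g")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return out_dir
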