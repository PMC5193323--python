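"""Selection of analysis units: ortholog pairs, youngest paralog pairs and
outgroup co-ortholog triplets, with calibrated ages attached.

Paralog pairs are oriented by expression: ``gene_ref`` is always the member
with the higher maximal expression (linear scale, over tissues), so that
divergence can be read as major copy vs minor copy.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError
from .io_tables import AgeCalibration

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("gene_ref", "gene_alt", "pair_class", "age_my", "node_label")

TRIPLET_COLUMNS = PAIR_COLUMNS + ("outgroup_gene", "outgroup_species", "outgroup_age_my")


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=list(PAIR_COLUMNS))


def select_ortholog_pairs(
    homology: pd.DataFrame,
    focal_species: str,
    other_species: str,
    calibration: AgeCalibration,
) -> pd.DataFrame:
    """One AnalysisPair per one-to-one ortholog row between the two species.

    ``gene_ref`` is the focal-species gene.  A gene appearing in more than
    one one-to-one row for the same species pair is a data error.
    """
    rel = homology["relation"] == "one2one_ortholog"
    fwd = rel & (homology["species_a"] == focal_species) & (homology["species_b"] == other_species)
    rev = rel & (homology["species_b"] == focal_species) & (homology["species_a"] == other_species)
    ref = pd.concat([homology.loc[fwd, "gene_a"], homology.loc[rev, "gene_b"]])
    alt = pd.concat([homology.loc[fwd, "gene_b"], homology.loc[rev, "gene_a"]])
    nodes = pd.concat([homology.loc[fwd, "node_label"], homology.loc[rev, "node_label"]])
    if ref.empty:
        logger.warning(
            "no one2one orthologs for %s vs %s", focal_species, other_species
        )
        return _empty_pairs()
    if ref.duplicated().any() or alt.duplicated().any():
        bad = pd.concat([ref[ref.duplicated()], alt[alt.duplicated()]]).unique()
        raise FormatError(
            f"genes listed in multiple one2one rows for {focal_species} vs "
            f"{other_species}: {list(bad[:5])}"
        )
    ages = nodes.map(calibration.age)
    pairs = pd.DataFrame(
        {
            "gene_ref": ref.to_numpy(),
            "gene_alt": alt.to_numpy(),
            "pair_class": "ortholog",
            "age_my": ages.to_numpy(dtype=float),
            "node_label": nodes.to_numpy(),
        }
    )
    return pairs.sort_values("gene_ref", kind="stable").reset_index(drop=True)


def select_youngest_paralog_pairs(
    homology: pd.DataFrame,
    species: str,
    calibration: AgeCalibration,
    tau_table: pd.DataFrame,
) -> pd.DataFrame:
    """Youngest within-species paralog couple per gene, expression-oriented.

    Every gene is paired with its most recently diverged paralog (minimum
    duplication-node age among its within-species rows); when several
    partners share that age the one with the highest maximal expression is
    taken (ties: lexicographically smaller id).  The resulting pair set is
    deduplicated, and within each age class a gene may appear in at most
    one pair (conflicts resolved in favour of the pair with the higher
    maximal expression, deterministically).  Pairs involving genes absent
    from ``tau_table`` are dropped with a logged count.
    """
    rows = homology[
        (homology["relation"] == "within_species_paralog")
        & (homology["species_a"] == species)
    ].copy()
    if rows.empty:
        logger.warning("no within-species paralog rows for %s", species)
        return _empty_pairs()
    rows["age_my"] = rows["node_label"].map(calibration.age)

    max_expr = tau_table["max_expression"]
    known = rows["gene_a"].isin(max_expr.index) & rows["gene_b"].isin(max_expr.index)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info(
            "select_youngest_paralog_pairs: dropped %d rows with genes missing "
            "from the tau table", n_dropped,
        )
    rows = rows[known]
    if rows.empty:
        return _empty_pairs()

    # symmetric view: one record per (gene, partner)
    sym = pd.concat(
        [
            rows.rename(columns={"gene_a": "gene", "gene_b": "partner"}),
            rows.rename(columns={"gene_b": "gene", "gene_a": "partner"}),
        ],
        ignore_index=True,
    )[["gene", "partner", "age_my", "node_label", "family_id"]]
    sym["partner_expr"] = sym["partner"].map(max_expr).to_numpy(dtype=float)
    # youngest partner per gene; multifurcation ties by partner expression,
    # then lexicographic partner id
    sym = sym.sort_values(
        ["gene", "age_my", "partner_expr", "partner"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    best = sym.groupby("gene", sort=True).head(1)

    # deduplicate unordered pairs
    seen: dict[frozenset, dict] = {}
    for rec in best.itertuples(index=False):
        key = frozenset((rec.gene, rec.partner))
        if key not in seen:
            seen[key] = rec._asdict()

    # enforce one pair per gene within each age class, preferring pairs
    # whose higher-expressed member is largest (stable, deterministic)
    records = sorted(
        seen.values(),
        key=lambda r: (
            r["node_label"],
            -max(max_expr[r["gene"]], max_expr[r["partner"]]),
            min(r["gene"], r["partner"]),
        ),
    )
    used: dict[str, set] = {}
    kept, n_conflict = [], 0
    for rec in records:
        cls = rec["node_label"]
        members = used.setdefault(cls, set())
        if rec["gene"] in members or rec["partner"] in members:
            n_conflict += 1
            continue
        members.update((rec["gene"], rec["partner"]))
        kept.append(rec)
    if n_conflict:
        logger.info(
            "select_youngest_paralog_pairs: %d pairs dropped to keep genes "
            "unique within an age class", n_conflict,
        )

    out = []
    for rec in kept:
        a, b = rec["gene"], rec["partner"]
        # gene_ref = higher max expression; equal -> lexicographically smaller id
        if max_expr[a] < max_expr[b] or (max_expr[a] == max_expr[b] and a > b):
            a, b = b, a
        out.append((a, b, "paralog", rec["age_my"], rec["node_label"]))
    pairs = pd.DataFrame(out, columns=list(PAIR_COLUMNS))
    return pairs.sort_values(["age_my", "gene_ref"], kind="stable").reset_index(drop=True)


def attach_outgroups(
    pairs: pd.DataFrame,
    homology: pd.DataFrame,
    calibration: AgeCalibration,
) -> pd.DataFrame:
    """Attach the closest unduplicated outgroup co-ortholog to paralog pairs.

    A triplet is kept only when exactly one candidate outgroup gene is
    co-ortholog (relation one2two_outgroup) to *both* paralogs, the
    outgroup speciation age is >= the duplication age, and the outgroup
    gene is not itself part of a within-species paralog pair in its own
    species.  Among several valid candidates the one with the smallest
    speciation age is taken.
    """
    og = homology[homology["relation"] == "one2two_outgroup"].copy()
    if og.empty or pairs.empty:
        return pd.DataFrame(columns=list(TRIPLET_COLUMNS))
    og["out_age"] = og["node_label"].map(calibration.age)

    duplicated_out = set(
        homology.loc[
            homology["relation"] == "within_species_paralog", ["gene_a", "gene_b"]
        ].to_numpy().ravel()
    )

    # map paralog gene -> list of (outgroup gene, species, node, age)
    links: dict[str, list] = {}
    for rec in og.itertuples(index=False):
        links.setdefault(rec.gene_a, []).append(
            (rec.gene_b, rec.species_b, rec.node_label, rec.out_age)
        )

    triplets, n_skipped = [], 0
    for pair in pairs.itertuples(index=False):
        cand_ref = {c[0]: c for c in links.get(pair.gene_ref, [])}
        cand_alt = {c[0]: c for c in links.get(pair.gene_alt, [])}
        shared = sorted(set(cand_ref) & set(cand_alt))
        valid = []
        for gene in shared:
            out_gene, out_sp, out_node, out_age = cand_ref[gene]
            if out_age < pair.age_my:
                continue  # speciation must predate the duplication
            if out_gene in duplicated_out:
                n_skipped += 1
                continue
            valid.append((out_age, out_gene, out_sp, out_node))
        if not valid:
            continue
        out_age, out_gene, out_sp, _ = min(valid)
        triplets.append(
            (
                pair.gene_ref, pair.gene_alt, pair.pair_class, pair.age_my,
                pair.node_label, out_gene, out_sp, out_age,
            )
        )
    if n_skipped:
        logger.info("attach_outgroups: skipped %d duplicated outgroup candidates", n_skipped)
    out = pd.DataFrame(triplets, columns=list(TRIPLET_COLUMNS))
    return out.sort_values(["age_my", "gene_ref"], kind="stable").reset_index(drop=True)


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
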