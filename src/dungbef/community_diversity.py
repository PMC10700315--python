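"""Community descriptors: richness, abundance, evenness and two
functional-dispersion (FDis) indices.

Both FDis variants are mean pairwise distances between the species present
at a pasture (a functional adaptation of mean phylogenetic distance):

* ``FDisMorphology`` — Euclidean distance in a standardized trait space
  built from nine linear morphological traits plus log dry biomass, each
  z-scored over the species pool of the landscape pair.
* ``FDisBehavior`` — cophenetic distance on a fixed behavioral phenetic
  tree whose root separates the kleptocoprid/endocoprid from the
  paracoprid/telecoprid guilds, with the four guilds below and the three
  body-size classes (small < 10 mm, medium 10-18 mm, large > 18 mm) as the
  12 tips.  Species are placed on tips through their guild and mean body
  length.
"""

from __future__ import annotations

import math
import warnings
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

from .data_model import GUILDS, TRAIT_COLUMNS, BODY_LENGTH_PARTS, StudyBundle

__all__ = [
    "SIZE_CLASSES",
    "FUNCTIONAL_GROUPS",
    "species_trait_profile",
    "species_profiles",
    "size_class",
    "assign_functional_group",
    "trait_distance_matrix",
    "mean_pairwise_distance",
    "build_behavior_tree",
    "behavior_tree_newick",
    "cophenetic_matrix",
    "fdis_behavior",
    "community_metrics",
]

SIZE_CLASSES = ("large", "medium", "small")

#: All guild x size-class combinations, e.g. ``"large_paracoprid"``.
FUNCTIONAL_GROUPS = tuple(f"{size}_{guild}" for guild in GUILDS for size in SIZE_CLASSES)

# Boundary body lengths of exactly 10.0 and 18.0 mm fall in "medium": the
# published medium range is inclusive while large/small use strict
# inequalities.
LARGE_MIN_MM = 18.0
SMALL_MAX_MM = 10.0


def size_class(mean_body_length_mm: float) -> str:
    """Body-size class from mean body length (head + pronotum + elytra)."""
    if not math.isfinite(mean_body_length_mm) or mean_body_length_mm <= 0:
        raise ValueError(f"body length must be positive, got {mean_body_length_mm!r}")
    if mean_body_length_mm > LARGE_MIN_MM:
        return "large"
    if mean_body_length_mm < SMALL_MAX_MM:
        return "small"
    return "medium"


def assign_functional_group(guild: str, mean_body_length_mm: float) -> str:
    """Combine guild and body-size class into one of the 12 functional groups."""
    if guild not in GUILDS:
        raise ValueError(f"unknown guild {guild!r}")
    return f"{size_class(mean_body_length_mm)}_{guild}"


def species_trait_profile(traits: pd.DataFrame, species_id: str) -> pd.Series:
    """Mean trait vector (nine traits + biomass) and mean body length of one
    species, averaged over its measured individuals.

    Missing trait values are skipped individual-wise: each column mean is
    taken over the individuals measured for that trait.  Body length is the
    mean of the per-individual sums head + pronotum + elytra lengths.
    """
    rows = traits[traits["species_id"] == species_id]
    if rows.empty:
        raise KeyError(f"no measured individuals for species {species_id!r}")
    cols = list(TRAIT_COLUMNS) + ["biomass"]
    profile = rows[cols].mean(skipna=True)
    body = rows[list(BODY_LENGTH_PARTS)].sum(axis=1, skipna=False)
    profile["body_length"] = float(body.mean(skipna=True))
    profile.name = species_id
    return profile


def species_profiles(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-species trait profiles (rows = species, sorted by id).

    Vectorized equivalent of applying :func:`species_trait_profile` to
    every species.
    """
    cols = list(TRAIT_COLUMNS) + ["biomass"]
    prof = traits.groupby("species_id")[cols].mean()
    body = traits[list(BODY_LENGTH_PARTS)].sum(axis=1, skipna=False)
    prof["body_length"] = body.groupby(traits["species_id"]).mean()
    return prof.sort_index()


def trait_distance_matrix(profiles: pd.DataFrame, standardize: bool = True,
                          log_biomass: bool = True) -> pd.DataFrame:
    """Pairwise Euclidean distances between species trait profiles.

    Columns used are the nine linear traits plus biomass; biomass is
    log-transformed (it spans orders of magnitude relative to the linear
    traits) and every column is z-scored over the species in ``profiles``
    before distances are taken.  Zero-variance columns cannot be z-scored
    and are dropped with a warning.
    """
    cols = list(TRAIT_COLUMNS) + ["biomass"]
    X = profiles[cols].to_numpy(dtype=float).copy()
    if log_biomass:
        X[:, -1] = np.log(X[:, -1])
    if standardize and len(X) > 1:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 1e-12 * (np.abs(X).mean(axis=0) + 1.0)
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"zero-variance trait column(s) dropped from the "
                          f"standardized trait space: {dropped}", stacklevel=2)
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


def mean_pairwise_distance(D: pd.DataFrame, present,
                           weights: pd.Series | None = None) -> float:
    """Mean distance over the unordered distinct pairs of present species.

    Returns 0 for communities with at most one species.  With ``weights``
    (abundances) the mean is weighted by the product of pair abundances;
    the default is unweighted presence.
    """
    present = list(present)
    missing = [s for s in present if s not in D.index]
    if missing:
        raise KeyError(f"species not in the distance matrix: {missing}")
    k = len(present)
    if k <= 1:
        return 0.0
    sub = D.loc[present, present].to_numpy(dtype=float)
    iu = np.triu_indices(k, 1)
    if weights is None:
        return float(sub[iu].mean())
    w = np.asarray([weights[s] for s in present], dtype=float)
    pw = (w[:, None] * w[None, :])[iu]
    return float((sub[iu] * pw).sum() / pw.sum())


def build_behavior_tree(branch_length: float = 1.0) -> dendropy.Tree:
    """The fixed behavioral phenetic tree with the 12 functional groups as
    tips.

    Topology: root -> (kleptocoprid, endocoprid) vs (paracoprid,
    telecoprid); each guild then splits into its three size classes.  All
    edges get ``branch_length`` (default 1), making the tree ultrametric.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    splits = [("kleptocoprid", "endocoprid"), ("paracoprid", "telecoprid")]
    for pair in splits:
        clade = tree.seed_node.new_child(edge_length=branch_length)
        for guild in pair:
            guild_node = clade.new_child(edge_length=branch_length)
            for size in SIZE_CLASSES:
                tip = guild_node.new_child(edge_length=branch_length)
                tip.taxon = taxa.new_taxon(f"{size}_{guild}")
    return tree


def behavior_tree_newick(branch_length: float = 1.0) -> str:
    """Newick export of the behavioral tree."""
    return build_behavior_tree(branch_length).as_string(schema="newick").strip()


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip patristic distances of a tree as a labelled DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tree.taxon_namespace]
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1 is not t2:
                D.loc[t1.label, t2.label] = pdm.patristic_distance(t1, t2)
    return D


def fdis_behavior(tree: dendropy.Tree, functional_groups: pd.Series,
                  weights: pd.Series | None = None) -> float:
    """Behavioral FDis: mean pairwise cophenetic distance between the tips
    occupied by the species present.

    ``functional_groups`` maps species id -> functional-group tip label.
    Two species on the same tip contribute a zero distance.
    """
    coph = cophenetic_matrix(tree)
    unmapped = [s for s, g in functional_groups.items() if g not in coph.index]
    if unmapped:
        raise KeyError(f"species with unmapped functional groups: {unmapped}")
    species = list(functional_groups.index)
    k = len(species)
    if k <= 1:
        return 0.0
    tips = functional_groups.to_numpy()
    sub = coph.loc[tips, tips].to_numpy(dtype=float)
    iu = np.triu_indices(k, 1)
    if weights is None:
        return float(sub[iu].mean())
    w = np.asarray([weights[s] for s in species], dtype=float)
    pw = (w[:, None] * w[None, :])[iu]
    return float((sub[iu] * pw).sum() / pw.sum())


def _shannon_evenness(abundances: np.ndarray) -> float:
    """Pielou's J: Shannon H' divided by ln(richness); NaN for richness <= 1."""
    a = abundances[abundances > 0].astype(float)
    if len(a) <= 1:
        return float("nan")
    p = a / a.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(len(a)))


def community_metrics(bundle: StudyBundle, tree: dendropy.Tree | None = None,
                      abundance_weighted: bool = False) -> pd.DataFrame:
    """Per-pasture community metrics for a whole study bundle.

    For each landscape, the morphological trait space is standardized over
    the joint species pool of its two pastures, so within-pair FDis values
    are comparable.  Returns one row per site-regime with ``abundance``,
    ``richness``, ``evenness``, ``fdis_morphology`` and ``fdis_behavior``.
    """
    tree = tree if tree is not None else build_behavior_tree()
    coph = cophenetic_matrix(tree)
    profiles = species_profiles(bundle.traits)
    guild_of = (bundle.occurrences.drop_duplicates("species_id")
                .set_index("species_id")["guild"])
    fgroup = pd.Series({
        sp: assign_functional_group(guild_of[sp], profiles.loc[sp, "body_length"])
        for sp in profiles.index if sp in guild_of.index})

    rows = []
    occ = bundle.occurrences[bundle.occurrences["abundance"] > 0]
    for landscape_id in bundle.landscape_ids:
        pair = bundle.site_pair(landscape_id)
        pool = sorted(occ[occ["site_id"].isin(pair.values())]["species_id"].unique())
        measured_pool = [s for s in pool if s in profiles.index]
        D_morph = (trait_distance_matrix(profiles.loc[measured_pool])
                   if len(measured_pool) > 1 else None)
        for regime in ("low", "high"):
            site_id = pair[regime]
            comm = occ[occ["site_id"] == site_id]
            species = sorted(comm["species_id"].unique())
            counts = comm.groupby("species_id")["abundance"].sum()
            weights = counts if abundance_weighted else None
            measured = [s for s in species if s in profiles.index]
            fdm = (mean_pairwise_distance(D_morph, measured, weights)
                   if D_morph is not None and len(measured) > 1 else 0.0)
            present_groups = fgroup.reindex(measured).dropna()
            k = len(present_groups)
            if k > 1:
                tips = present_groups.to_numpy()
                sub = coph.loc[tips, tips].to_numpy(dtype=float)
                iu = np.triu_indices(k, 1)
                if weights is None:
                    fdb = float(sub[iu].mean())
                else:
                    w = np.asarray([weights[s] for s in present_groups.index])
                    pw = (w[:, None] * w[None, :])[iu]
                    fdb = float((sub[iu] * pw).sum() / pw.sum())
            else:
                fdb = 0.0
            rows.append({
                "site_id": site_id,
                "landscape_id": landscape_id,
                "regime": regime,
                "abundance": int(counts.sum()),
                "richness": int(len(species)),
                "evenness": _shannon_evenness(counts.to_numpy()),
                "fdis_morphology": fdm,
                "fdis_behavior": fdb,
            })
    return pd.DataFrame(rows)
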