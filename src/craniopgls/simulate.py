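"""Synthetic study generator: trees, Brownian traits, specimen tables.

Generates every input the analysis pipeline consumes, with the
statistical structure the methods assume, so parameter-recovery and
error-rate experiments need no external data:

* pure-birth (Yule) trees with exponential branch lengths, rescaled to
  unit height;
* Brownian-motion trait evolution along the tree (univariate or with a
  p x p rate matrix), giving tip covariance rate * C by construction;
* a leporid-like study: 16 species, 2-12 specimens each, ten log-normal
  cranial measurements whose species log-means evolve by Brownian motion
  (plus an isometric log-size walk that the shape ratios must remove),
  and facial-tilt angles built as locomotor-group base means plus a
  Brownian deviation plus within-species normal noise.

Default group structure mirrors the study design: 3 generalized, 10
saltatorial and 3 cursorial species, 9 of 16 burrowers; FT base means
44.0 / 37.2 / 36.3 degrees with 5.5 degrees of within-species spread.
Group labels can be assigned uniformly at random (breaking the
phylogeny-ecology confound) or painted onto contiguous clades (creating
it) — the contrast between ordinary and phylogenetic ANOVA only shows up
in the second mode.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .morphometrics import MEASUREMENT_COLUMNS
from .phylo import PhyloTree

#: typical adult leporid cranial measurements (mm), used as root values
ROOT_MEASUREMENTS_MM = {
    "BLD": 10.0, "BOL": 12.0, "DIL": 22.0, "IOW": 13.0, "NL": 32.0,
    "NW": 13.0, "PAL": 12.0, "SCF": 8.0, "SLD": 75.0, "SW": 35.0,
}

DEFAULT_FT_GROUP_MEANS = {
    "generalized": 44.0,
    "saltatorial": 37.2,
    "cursorial": 36.3,
}

#: study-like composition: counts per locomotor group and burrowers
DEFAULT_GROUP_COUNTS = {"generalized": 3, "saltatorial": 10, "cursorial": 3}
DEFAULT_N_BURROWERS = 9


@dataclass
class SimConfig:
    """Parameters of a synthetic study.

    Rates are variances per unit tree height (trees are rescaled to unit
    height before simulation).  ``ft_bm_var`` is the among-species
    Brownian variance of facial tilt (deg^2); ``within_species_sd_ft``
    the specimen-level SD (deg).  Shape evolves on the log scale:
    ``bm_rate_shape`` per-variable Brownian variance (log^2 units),
    ``size_bm_var`` an additional isometric log-size walk shared by all
    ten measurements, ``within_species_sd_shape`` the specimen-level
    log-SD.  ``group_mode`` is 'random' or 'clades'.
    """

    seed: int
    n_taxa: int = 16
    specimens_per_taxon: tuple[int, int] = (2, 12)
    group_counts: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    n_burrowers: int = DEFAULT_N_BURROWERS
    ft_group_means: dict = field(default_factory=lambda: dict(DEFAULT_FT_GROUP_MEANS))
    ft_bm_var: float = 4.0
    within_species_sd_ft: float = 5.5
    bm_rate_shape: float = 0.02
    size_bm_var: float = 0.04
    within_species_sd_shape: float = 0.04
    group_mode: str = "random"

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        lo, hi = self.specimens_per_taxon
        if not (1 <= lo <= hi):
            raise ValueError("invalid specimens_per_taxon range")
        if sum(self.group_counts.values()) != self.n_taxa:
            raise ValueError("group counts must sum to n_taxa")
        if min(self.group_counts.values()) < 2:
            raise ValueError("every locomotor level needs >= 2 species")
        if not (0 <= self.n_burrowers <= self.n_taxa):
            raise ValueError("n_burrowers out of range")
        for val in (self.ft_bm_var, self.within_species_sd_ft,
                    self.bm_rate_shape, self.size_bm_var,
                    self.within_species_sd_shape):
            if val <= 0:
                raise ValueError("rates and SDs must be positive")
        if self.group_mode not in ("random", "clades"):
            raise ValueError("group_mode must be 'random' or 'clades'")


@dataclass
class SimulatedStudy:
    measurements: pd.DataFrame
    facial_tilt: pd.DataFrame
    ecology: pd.DataFrame
    tree: PhyloTree
    species_truth: pd.DataFrame  # true species means (FT + log shape)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(outdir / "measurements.csv", index=False)
        self.facial_tilt.to_csv(outdir / "facial_tilt.csv", index=False)
        self.ecology[["species", "locomotion", "burrowing"]].to_csv(
            outdir / "ecology.csv", index=False
        )
        self.tree.write(outdir / "tree.nwk")


def simulate_tree(n_taxa: int, seed: int | None = None,
                  unit_height: bool = True,
                  min_branch_frac: float = 0.02) -> PhyloTree:
    """Pure-birth (Yule, unit rate) ultrametric tree with n_taxa tips.

    The birth-death process stops at the n-th speciation; terminal
    branches are then extended by the Exp(n) waiting time to the next
    (unrealised) event so tip branches are positive.  Trees whose
    shortest branch is below ``min_branch_frac`` of tree height are
    rejected and redrawn: published supermatrix phylogenies used in
    comparative studies are resolved with non-negligible branch lengths,
    and near-zero branches make the Brownian covariance ill-conditioned.
    Set ``min_branch_frac=0`` for unconditioned Yule trees.  Tips are
    labelled S01..Snn in Newick order.  Deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(None if seed is None else int(seed))
    for _ in range(1000):
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, rng=rng,
        )
        ext = rng.expovariate(n_taxa)
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + ext
        tree.seed_node.edge.length = None
        lengths = [e.length for e in tree.preorder_edge_iter()
                   if e.length is not None]
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        if min(lengths) >= min_branch_frac * max(depths):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a tree satisfying min_branch_frac")
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:0{width}d}"
    out = PhyloTree(tree)
    return out.scale_to_unit_height() if unit_height else out


def simulate_bm(tree: PhyloTree, rate, root_value=0.0,
                seed: int | None = None) -> pd.DataFrame:
    """Brownian-motion tip values: taxa x p DataFrame.

    Each edge adds a zero-mean normal increment with covariance
    rate * branch_length; ``rate`` may be a positive scalar (independent
    traits) or a p x p PSD matrix.
    """
    root = np.atleast_1d(np.asarray(root_value, dtype=float))
    p = root.size
    rate_arr = np.asarray(rate, dtype=float)
    if rate_arr.ndim == 0:
        if rate_arr < 0:
            raise ValueError("rate must be non-negative")
        L = None  # independent traits: scalar scaling, no p x p factor
        sd = float(np.sqrt(rate_arr))
    else:
        if rate_arr.shape != (p, p):
            raise ValueError("rate matrix shape must match root_value length")
        w, V = np.linalg.eigh(rate_arr)
        if np.any(w < -1e-12 * max(w.max(), 1.0)):
            raise ValueError("rate matrix is not PSD")
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    rng = np.random.default_rng(seed)
    dtree = tree._tree
    values = {dtree.seed_node: root}
    out = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            z = rng.standard_normal(p)
            step = (sd * z if L is None else L @ z) * np.sqrt(node.edge.length)
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    Y = pd.DataFrame.from_dict(out, orient="index").reindex(tree.tips)
    Y.index.name = "species"
    return Y


def _assign_groups(tree: PhyloTree, counts: dict, mode: str,
                   rng: np.random.Generator) -> pd.Series:
    """Locomotor labels per species, random or clade-contiguous.

    Clade mode exploits the fact that tips adjacent in Newick order are
    phylogenetically clustered: non-reference groups get contiguous
    blocks starting at a random offset, confounding ecology with
    ancestry.
    """
    tips = list(tree.tips)
    n = len(tips)
    labels = np.empty(n, dtype=object)
    groups = sorted(counts)  # deterministic order
    if mode == "random":
        pool = [g for g in groups for _ in range(counts[g])]
        rng.shuffle(pool)
        labels[:] = pool
    else:
        start = int(rng.integers(n))
        order = np.roll(np.arange(n), -start)
        pos = 0
        for g in groups:
            labels[order[pos:pos + counts[g]]] = g
            pos += counts[g]
    return pd.Series(labels, index=tips, name="locomotion")


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate mutually consistent measurement, FT, ecology tables + tree."""
    ss = np.random.SeedSequence(config.seed)
    seeds = (ss.generate_state(6) % np.uint32(2**31)).astype(np.int64)
    rng = np.random.default_rng(seeds[0])

    tree = simulate_tree(config.n_taxa, seed=int(seeds[1]), unit_height=True)
    taxa = tree.tips
    n = len(taxa)

    locomotion = _assign_groups(tree, config.group_counts, config.group_mode, rng)
    burrow = np.zeros(n, dtype=bool)
    burrow[rng.choice(n, size=config.n_burrowers, replace=False)] = True
    ecology = pd.DataFrame({
        "species": taxa,
        "locomotion": locomotion.loc[taxa].to_numpy(),
        "burrowing": np.where(burrow, "yes", "no"),
    })

    # facial tilt: group base + BM deviation; specimens add normal noise
    ft_dev = simulate_bm(tree, config.ft_bm_var, 0.0, seed=int(seeds[2]))[0]
    base = locomotion.map(config.ft_group_means).astype(float)
    ft_species = base.loc[taxa] + ft_dev

    # shape: BM on log measurements + shared isometric log-size walk
    root_log = np.log([ROOT_MEASUREMENTS_MM[c] for c in MEASUREMENT_COLUMNS])
    logshape = simulate_bm(tree, config.bm_rate_shape, root_log,
                           seed=int(seeds[3]))
    logsize = simulate_bm(tree, config.size_bm_var, 0.0, seed=int(seeds[4]))[0]
    log_species = logshape.add(logsize, axis=0)
    log_species.columns = MEASUREMENT_COLUMNS

    lo, hi = config.specimens_per_taxon
    spec_rng = np.random.default_rng(seeds[5])
    meas_rows, ft_rows = [], []
    for sp in taxa:
        n_spec = int(spec_rng.integers(lo, hi + 1))
        for k in range(1, n_spec + 1):
            sid = f"{sp}_{k:02d}"
            noise = spec_rng.normal(0.0, config.within_species_sd_shape,
                                    len(MEASUREMENT_COLUMNS))
            vals = np.exp(log_species.loc[sp].to_numpy() + noise)
            meas_rows.append({"specimen_id": sid, "species": sp,
                              **dict(zip(MEASUREMENT_COLUMNS, np.round(vals, 4)))})
            ft_rows.append({
                "specimen_id": sid, "species": sp,
                "FT": round(float(ft_species[sp]
                                  + spec_rng.normal(0.0, config.within_species_sd_ft)), 3),
            })

    truth = log_species.copy()
    truth.insert(0, "FT", ft_species)
    return SimulatedStudy(
        measurements=pd.DataFrame(meas_rows),
        facial_tilt=pd.DataFrame(ft_rows),
        ecology=ecology,
        tree=tree,
        species_truth=truth,
    )
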