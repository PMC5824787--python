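"""Synthetic inputs for every pipeline stage, with recorded ground truth.

All generators are pure functions of their parameters and seed.  The
default family fixture — 12 taxa, 60 residues, WAG model, root-to-tip
depth 0.25 substitutions/site — is small enough for the exhaustive oracles
used in testing, while deep enough that ancestral reconstruction is
non-trivial.  No indels are simulated, so the simulated sequences are
their own alignment; this is a deliberate simplification relative to real
protein families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

from .family import AlignedFamily
from .models import AMINO_ACIDS, SubstitutionModel, wag_model
from .phylo import PhyloTree


# ---------------------------------------------------------------------------
# Random trees

def random_ultrametric_tree(n_taxa: int, depth: float, seed: int,
                            prefix: str = "T") -> PhyloTree:
    """Random binary ultrametric tree (coalescent-style joins), total
    root-to-tip depth `depth` substitutions/site."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    clusters = [(dendropy.Node(taxon=taxa.get_taxon(lb)), 0.0)
                for lb in labels]
    t = 0.0
    while len(clusters) > 1:
        t += rng.exponential(1.0)
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (ni, ti), (nj, tj) = clusters[i], clusters[j]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = t - ti
        nj.edge.length = t - tj
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((parent, t))
    root, total = clusters[0]
    scale = depth / total if total > 0 else 0.0
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return PhyloTree(tree)


def random_additive_tree(n_taxa: int, seed: int, min_bl: float = 0.05,
                         max_bl: float = 0.5, prefix: str = "T") -> PhyloTree:
    """Random binary topology with iid branch lengths (non-ultrametric)."""
    tree = random_ultrametric_tree(n_taxa, 1.0, seed, prefix)
    rng = np.random.default_rng(seed + 1)
    for edge in tree.tree.preorder_edge_iter():
        if edge.head_node is tree.tree.seed_node:
            continue
        edge.length = float(rng.uniform(min_bl, max_bl))
    return tree


# ---------------------------------------------------------------------------
# Sequence families

@dataclass
class FamilySimSpec:
    n_taxa: int = 12
    length: int = 60
    depth: float = 0.25
    model: SubstitutionModel = field(default_factory=wag_model)
    seed: int = 0
    tree: PhyloTree = None  # overrides n_taxa/depth when given


def simulate_family(spec: FamilySimSpec) -> tuple:
    """Evolve a family along a tree with recorded ancestral truth.

    Returns (family, tree, truth) where truth maps internal node labels
    (N1.. in the same midpoint-rooted preorder scheme the reconstruction
    module uses) to true ancestral sequences.  The root state is drawn
    from the model's equilibrium frequencies and evolved down every branch
    by sampling from P(t); there are no indels, so the family is aligned
    as generated.
    """
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    tree = spec.tree or random_ultrametric_tree(spec.n_taxa, spec.depth,
                                                spec.seed)
    if not tree.internal_labels:
        tree.label_internal_nodes()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    model = spec.model
    pi = model.frequencies
    states = {}
    root = tree.tree.seed_node
    states[root] = rng.choice(20, size=spec.length, p=pi)
    for nd in tree.tree.preorder_node_iter():
        if nd is root:
            continue
        p = model.transition_matrix(nd.edge.length or 0.0)
        parent_states = states[nd.parent_node]
        child = np.empty(spec.length, dtype=int)
        u = rng.random(spec.length)
        cum = np.cumsum(p, axis=1)
        for site in range(spec.length):
            child[site] = min(
                int(np.searchsorted(cum[parent_states[site]], u[site])), 19)
        states[nd] = child
    def to_seq(arr):
        return "".join(AMINO_ACIDS[i] for i in arr)
    ids, seqs, truth = [], [], {}
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf():
            ids.append(nd.taxon.label)
            seqs.append(to_seq(states[nd]))
        else:
            truth[nd.label] = to_seq(states[nd])
    family = AlignedFamily(ids, seqs, reference_id=ids[0])
    return family, tree, truth


# ---------------------------------------------------------------------------
# Toy structures

@dataclass
class ToyStructureSpec:
    sequence: str
    geometry: str = "helix"        # "helix" | "extended"
    rise_per_residue: float = 1.5  # Å (3.8 for extended)
    turn_deg: float = 100.0        # helix twist per residue
    radius: float = 2.3            # helix radius, Å
    catalytic_position: int = 30
    chain: str = "A"


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def make_toy_structure(spec: ToyStructureSpec) -> tuple:
    """CA-only coordinates on an ideal helix or extended chain.

    Returns (pdb_text, truth) where truth is the full CA-CA distance
    matrix (n x n ndarray) for oracle tests.  Deterministic given the spec.
    """
    n = len(spec.sequence)
    coords = np.zeros((n, 3))
    if spec.geometry == "extended":
        rise = spec.rise_per_residue if spec.rise_per_residue != 1.5 else 3.8
        coords[:, 0] = np.arange(n) * rise
    elif spec.geometry == "helix":
        theta = np.deg2rad(spec.turn_deg) * np.arange(n)
        coords[:, 0] = spec.radius * np.cos(theta)
        coords[:, 1] = spec.radius * np.sin(theta)
        coords[:, 2] = np.arange(n) * spec.rise_per_residue
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    coords = np.round(coords, 3)  # PDB precision; truth matrix matches file
    lines = []
    for i, aa in enumerate(spec.sequence):
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {_ONE_TO_THREE[aa]} {spec.chain}"
            f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {'C':>2s}")
    lines.append("END")
    diff = coords[:, None, :] - coords[None, :, :]
    truth = np.sqrt((diff ** 2).sum(axis=2))
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Plate screens

def simulate_plate(true_folds: dict, noise_cv: float, seed: int,
                   plate_id: str = "P1", n_wt: int = 4, n_blank: int = 4,
                   wt_slope: float = 1.0, intercept: float = 100.0,
                   time_points=None) -> pd.DataFrame:
    """Long-format plate CSV table with programmed fold activities.

    WT wells have slope `wt_slope` (fluorescence units/s), variants
    fold x WT, blanks slope 0; fluorescence = intercept + slope*t plus
    Gaussian noise with standard deviation noise_cv x |signal|.  Sampling
    every 5 minutes over half an hour by default.
    """
    rng = np.random.default_rng(seed)
    if time_points is None:
        time_points = np.arange(0, 1801, 300, dtype=float)
    t = np.asarray(time_points, float)
    rows = []
    well_no = [0]

    def add_well(role, variant, slope):
        well_no[0] += 1
        well = f"{plate_id}-{well_no[0]:03d}"
        signal = intercept + slope * t
        noisy = signal + rng.normal(0.0, noise_cv * np.abs(signal))
        for ti, fi in zip(t, noisy):
            rows.append({"plate_id": plate_id, "well": well, "role": role,
                         "variant_id": variant, "time_s": ti,
                         "fluorescence": fi})

    for _ in range(n_wt):
        add_well("WT", "", wt_slope)
    for _ in range(n_blank):
        add_well("blank", "", 0.0)
    for variant, fold in true_folds.items():
        add_well("variant", variant, fold * wt_slope)
    return pd.DataFrame(rows)


def simulate_screen(n_variants: int, hit_rate: float, noise_cv: float,
                    seed: int, hit_fold_range=(2.0, 4.0),
                    null_fold_range=(0.3, 1.5), plate_size: int = 88
                    ) -> tuple:
    """A multi-plate screen with programmed actives.

    Returns (plate table, truth: variant -> programmed fold).
    """
    rng = np.random.default_rng(seed)
    truth = {}
    for i in range(n_variants):
        name = f"V{i + 1:04d}"
        if rng.random() < hit_rate:
            truth[name] = float(rng.uniform(*hit_fold_range))
        else:
            truth[name] = float(rng.uniform(*null_fold_range))
    names = list(truth)
    frames = []
    for p, start in enumerate(range(0, n_variants, plate_size)):
        chunk = {v: truth[v] for v in names[start:start + plate_size]}
        frames.append(simulate_plate(chunk, noise_cv,
                                     seed=int(rng.integers(2 ** 31)),
                                     plate_id=f"P{p + 1}"))
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Kinetic rate tables

def simulate_mm(kcat_per_s: float, km_uM: float, e0_uM: float,
                s_grid_uM, noise_cv: float, seed: int) -> pd.DataFrame:
    """Initial-rate table v = kcat*E0*[S]/(KM+[S]) x (1 + eps),
    eps ~ N(0, noise_cv)."""
    rng = np.random.default_rng(seed)
    s = np.asarray(s_grid_uM, float)
    v = kcat_per_s * e0_uM * s / (km_uM + s)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=s.size))
    v = np.clip(v, 0.0, None)
    return pd.DataFrame({"substrate_conc_uM": s, "v_uM_per_s": v})


#: Default substrate grid for round-trip fits (µM).
DEFAULT_S_GRID = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
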