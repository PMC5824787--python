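"""Mutagenic oligo design and a statistical model of spiked-library composition.

The bench protocol (gene fragmentation, doping of mutagenic oligos, and
primerless reassembly) is abstracted as independent per-position
incorporation: each designed position mutates independently with a
per-position probability calibrated so the expected number of mutations per
library variant equals a target (default 4, the midpoint of the intended
3–5 mutations per variant).  Linkage between nearby positions that share a
fragment is deliberately ignored; the resulting mutations-per-variant
distribution is Binomial(n_positions, p) when p is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .structure import CandidateSet

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _codons_for(aa: str) -> list:
    return sorted(c for c, a in _STANDARD.forward_table.items() if a == aa)


def choose_mutant_codon(wt_codon: str, target_aa: str) -> str:
    """Codon for target_aa with minimal Hamming distance to the wild-type codon.

    Ties are broken lexicographically (A<C<G<T).
    """
    wt_codon = wt_codon.upper()
    if len(wt_codon) != 3 or any(b not in _BASES for b in wt_codon):
        raise ValueError(f"invalid codon {wt_codon!r}")
    if _STANDARD.forward_table.get(wt_codon) == target_aa:
        return wt_codon
    candidates = _codons_for(target_aa)
    if not candidates:
        raise ValueError(f"amino acid {target_aa!r} is not encodable")
    def hamming(c):
        return sum(1 for a, b in zip(c, wt_codon) if a != b)
    return min(candidates, key=lambda c: (hamming(c), c))


def design_oligo(gene: str, codon_index: int, mutant_codon: str,
                 flank_nt: int = 15) -> str:
    """Mutagenic oligo: upstream flank + mutant codon + downstream flank.

    codon_index is 1-based; flanks are truncated at the gene ends.
    """
    gene = gene.upper()
    n_codons = len(gene) // 3
    if not (1 <= codon_index <= n_codons):
        raise ValueError(f"codon index {codon_index} outside gene (1..{n_codons})")
    start = (codon_index - 1) * 3
    up = gene[max(0, start - flank_nt):start]
    down = gene[start + 3:start + 3 + flank_nt]
    if len(up) < flank_nt or len(down) < flank_nt:
        import warnings
        warnings.warn(f"oligo flanks truncated at gene ends for codon "
                      f"{codon_index}")
    return up + mutant_codon + down


@dataclass
class LibraryDesign:
    """A calibrated spiked-library design over a candidate substitution set."""

    gene: str
    target_protein: str
    #: rows: position, wt, anc, wt_codon, mut_codon, oligo, p_pos, weight
    substitutions: pd.DataFrame
    target_mean_mutations: float

    @property
    def positions(self) -> list:
        return sorted(self.substitutions["position"].unique())

    @property
    def p_by_position(self) -> dict:
        return {int(p): float(g["p_pos"].iloc[0])
                for p, g in self.substitutions.groupby("position")}

    def expected_mutations(self) -> float:
        return float(sum(self.p_by_position.values()))


def build_design(gene: str, candidates: CandidateSet,
                 target_mean: float = 4.0, flank_nt: int = 15) -> LibraryDesign:
    """Design oligos and calibrate incorporation probabilities.

    Each designed position gets uniform incorporation probability
    p = target_mean / n_positions; positions with several ancestral
    alternatives split that probability uniformly among them.
    """
    gene = gene.upper()
    if len(gene) % 3 != 0:
        raise ValueError("gene length must be divisible by 3")
    protein = str(Seq(gene).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    n_pos = candidates.n_positions
    if n_pos == 0:
        raise ValueError("empty candidate set")
    if target_mean > n_pos:
        raise ValueError(
            f"target mean {target_mean} exceeds number of positions {n_pos}")
    p_pos = target_mean / n_pos
    alt_counts = {}
    for e in candidates.entries:
        alt_counts[e["position"]] = alt_counts.get(e["position"], 0) + 1
    rows = []
    for e in candidates.entries:
        pos = e["position"]
        if pos > len(protein):
            raise ValueError(f"candidate position {pos} beyond protein length")
        if protein[pos - 1] != e["wt"]:
            raise ValueError(
                f"gene translates to {protein[pos - 1]} at position {pos}, "
                f"candidate says wild type is {e['wt']}")
        wt_codon = gene[(pos - 1) * 3:pos * 3]
        mut_codon = choose_mutant_codon(wt_codon, e["anc"])
        oligo = design_oligo(gene, pos, mut_codon, flank_nt)
        rows.append({"position": pos, "wt": e["wt"], "anc": e["anc"],
                     "wt_codon": wt_codon, "mut_codon": mut_codon,
                     "oligo": oligo, "p_pos": p_pos,
                     "weight": 1.0 / alt_counts[pos]})
    df = pd.DataFrame(rows)
    design = LibraryDesign(gene, protein, df, float(target_mean))
    assert abs(design.expected_mutations() - target_mean) < 1e-9
    return design


@dataclass(frozen=True)
class LibraryVariant:
    """One simulated library member: applied substitutions and its protein."""

    substitutions: tuple  # of (position, anc_aa)
    protein: str

    @property
    def n_mutations(self) -> int:
        return len(self.substitutions)


def simulate_library(design: LibraryDesign, n_variants: int, seed: int
                     ) -> tuple:
    """Draw library variants under the independent-incorporation model.

    Returns (variants, summary) where summary holds the mean, SD, histogram
    of mutations per variant and per-substitution observed frequencies.
    Reproducible given the seed.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    positions = design.positions
    groups = {int(p): g.reset_index(drop=True)
              for p, g in design.substitutions.groupby("position")}
    p_by_pos = design.p_by_position
    n_pos = len(positions)
    mutate = rng.random((n_variants, n_pos)) < np.array(
        [p_by_pos[p] for p in positions])
    variants = []
    sub_counts = {(int(r.position), r.anc): 0
                  for r in design.substitutions.itertuples()}
    for v in range(n_variants):
        applied = []
        prot = list(design.target_protein)
        for k, pos in enumerate(positions):
            if not mutate[v, k]:
                continue
            g = groups[pos]
            if len(g) == 1:
                row = g.iloc[0]
            else:
                w = g["weight"].to_numpy()
                row = g.iloc[rng.choice(len(g), p=w / w.sum())]
            applied.append((pos, row["anc"]))
            prot[pos - 1] = row["anc"]
            sub_counts[(pos, row["anc"])] += 1
        variants.append(LibraryVariant(tuple(applied), "".join(prot)))
    counts = np.array([v.n_mutations for v in variants])
    hist = np.bincount(counts, minlength=n_pos + 1)
    summary = {
        "n_variants": n_variants,
        "mean_mutations": float(counts.mean()),
        "sd_mutations": float(counts.std(ddof=1)) if n_variants > 1 else 0.0,
        "histogram": hist.tolist(),
        "substitution_frequency": {f"{p}{a}": c / n_variants
                                   for (p, a), c in sub_counts.items()},
    }
    return variants, summary


def sequencing_window_fraction(design: LibraryDesign, n_draws: int = 1000,
                               draw_size: int = 5, low: int = 2, high: int = 6,
                               seed: int = 0) -> float:
    """Descriptive check mirroring small-scale library sequencing.

    Fraction of repeated draws of `draw_size` variants in which every
    variant's mutation count lies in [low, high].
    """
    rng = np.random.default_rng(seed)
    n_pos = len(design.positions)
    p = design.target_mean_mutations / n_pos
    ok = 0
    for _ in range(n_draws):
        counts = rng.binomial(n_pos, p, size=draw_size)
        if np.all((counts >= low) & (counts <= high)):
            ok += 1
    return ok / n_draws
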