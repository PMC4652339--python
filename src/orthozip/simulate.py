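"""Synthetic data with known ground truth.

Three generators feed the downstream analyses:

* :func:`simulate_proteomes` evolves an ancestral gene set down a known
  species tree.  Along every branch each gene may duplicate (Poisson
  counts, mean ``duplication_rate``) and accumulates residue
  replacements at ``substitution_rate`` per site.  A configurable
  fraction of ancestral genes carries a planted bZIP motif that is
  inherited verbatim (never mutated); all other residues are drawn from
  an alphabet *excluding asparagine*, so the motif detector can have no
  hit outside carriers — specificity holds by construction, not by
  chance.  The cohort records, per species pair, which genes are truly
  co-orthologous (duplicates postdating the pair's last common ancestor
  belong to the same group).

* :func:`simulate_expression_panel` plants heterosis expression modes:
  per gene, two parent means are drawn on the log2 scale and the F1
  mean is placed according to the planted mode (above both parents by
  the planted log2 excess for over-dominance, below both for
  under-dominance, equal to one parent for dominance, at the mid-parent
  value for additivity); replicates add Gaussian noise.

* :func:`simulate_ct_panel` builds qPCR cycle-threshold tables whose
  2^-ddCt analysis returns the planted fold changes exactly at zero
  noise.  Measurement noise is applied to target-gene Cts; the
  reference gene models the stable internal control and stays fixed.

All randomness flows from a single integer seed through one
``numpy.random.Generator``, so identical configurations reproduce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import MODE_ADDITIVE, MODE_HIGH, MODE_LOW, MODE_OVER, MODE_UNDER
from .family import ProteinRecord

SpeciesTree = Union[str, tuple]

#: background alphabet: 19 amino acids, no Asn (see module docstring)
BACKGROUND_ALPHABET = "ACDEFGHIKLMPQRSTVWY"
_HYDROPHOBIC = "LIVFM"

CONTIG_PREFIX = "contig|"


def _tree_leaves(tree: SpeciesTree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree:
        out.extend(_tree_leaves(child))
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the proteome simulator.

    ``speciation_order`` is the species tree as nested tuples of labels
    from ``species_labels``, e.g. ``(("wheat", ("barley", "brachy")),
    ("urartu", "tauschii"))``; ``None`` builds a ladder in label order.
    Rates are per gene per lineage (duplication) or per residue per
    lineage (substitution).
    """

    species_labels: tuple[str, ...]
    n_ancestral_genes: int
    speciation_order: Optional[SpeciesTree] = None
    duplication_rate: float = 0.0
    substitution_rate: float = 0.0
    bzip_fraction: float = 0.5
    contig_fraction: float = 0.0
    mean_protein_length: int = 120
    n_heptads: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species_labels) < 1:
            raise ValueError("at least one species required")
        if len(set(self.species_labels)) != len(self.species_labels):
            raise ValueError("species labels must be unique")
        if self.n_ancestral_genes < 0:
            raise ValueError("n_ancestral_genes must be >= 0")
        if self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if not 0 <= self.bzip_fraction <= 1:
            raise ValueError("bzip_fraction must lie in [0, 1]")
        if not 0 <= self.contig_fraction <= 1:
            raise ValueError("contig_fraction must lie in [0, 1]")
        if self.mean_protein_length <= 0:
            raise ValueError("mean_protein_length must be positive")
        if self.n_heptads < 2:
            raise ValueError("n_heptads must be >= 2 for a detectable zipper")

    def tree(self) -> SpeciesTree:
        if self.speciation_order is not None:
            leaves = _tree_leaves(self.speciation_order)
            if sorted(leaves) != sorted(self.species_labels):
                raise ValueError("speciation_order leaves must equal species_labels")
            return self.speciation_order
        ladder: SpeciesTree = self.species_labels[-1]
        for label in reversed(self.species_labels[:-1]):
            ladder = (label, ladder)
        return ladder


@dataclass
class SyntheticCohort:
    """Proteomes plus the truth needed to grade downstream inference."""

    proteomes: dict[str, list[ProteinRecord]]
    truth_groups: dict[tuple[str, str], list[frozenset]]
    truth_bzip_ids: set[str]

    def fasta_bytes(self) -> bytes:
        """Canonical serialization (used for determinism checks)."""
        from .io import proteome_fasta_string

        chunks = []
        for species in sorted(self.proteomes):
            chunks.append(proteome_fasta_string(self.proteomes[species]))
        return "".join(chunks).encode()


class _Gene:
    __slots__ = ("copy_id", "residues", "motif_span", "ancestors")

    def __init__(self, copy_id: int, residues: str, motif_span, ancestors: dict):
        self.copy_id = copy_id
        self.residues = residues
        self.motif_span = motif_span  # (start, end) kept verbatim, or None
        self.ancestors = ancestors  # node id -> copy id held when entering node


def _random_background(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(BACKGROUND_ALPHABET), size=n)
    return "".join(BACKGROUND_ALPHABET[i] for i in idx)


def _plant_motif(rng: np.random.Generator, n_heptads: int) -> str:
    """Basic region (N-x7-R/K) plus an ``n_heptads``-anchor zipper."""
    spacer7 = _random_background(rng, 7)
    rk = "R" if rng.random() < 0.5 else "K"
    spacer8 = _random_background(rng, 8)
    zipper = []
    for h in range(n_heptads):
        zipper.append(_HYDROPHOBIC[rng.integers(0, len(_HYDROPHOBIC))])
        if h < n_heptads - 1:
            zipper.append(_random_background(rng, 6))
    return "N" + spacer7 + rk + spacer8 + "".join(zipper)


def _mutate(gene_residues: str, motif_span, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return gene_residues
    chars = list(gene_residues)
    protected_lo, protected_hi = motif_span if motif_span else (-1, -1)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if protected_lo <= i < protected_hi:
            continue
        current = chars[i]
        choices = BACKGROUND_ALPHABET.replace(current, "")
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def simulate_proteomes(config: SimulationConfig) -> SyntheticCohort:
    """Evolve an ancestral gene set down the species tree.

    See the module docstring for the model.  Gene ids are
    ``{species}_g{k}`` (``contig|``-prefixed for contig-derived
    records); chromosome labels use the species' initial as genome tag.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree()
    motif_min = 17 + 7 * (config.n_heptads - 1) + 1

    copy_counter = [0]

    def new_copy_id() -> int:
        copy_counter[0] += 1
        return copy_counter[0]

    # ancestral genes at the root
    n_carriers = int(round(config.bzip_fraction * config.n_ancestral_genes))
    root_genes: list[_Gene] = []
    for g in range(config.n_ancestral_genes):
        length = max(motif_min + 10, int(rng.poisson(config.mean_protein_length)))
        body = _random_background(rng, length)
        motif_span = None
        if g < n_carriers:
            motif = _plant_motif(rng, config.n_heptads)
            start = int(rng.integers(0, length - len(motif) + 1))
            body = body[:start] + motif + body[start + len(motif):]
            motif_span = (start, start + len(motif))
        root_genes.append(_Gene(new_copy_id(), body, motif_span, {}))

    carriers_root = {g.copy_id for g in root_genes if g.motif_span is not None}

    node_counter = [0]
    leaf_genes: dict[str, list[_Gene]] = {}
    # node id of the LCA for each species pair
    lca: dict[frozenset, int] = {}

    def process(node: SpeciesTree, genes: list[_Gene]) -> None:
        if isinstance(node, str):
            leaf_genes[node] = genes
            return
        node_id = node_counter[0]
        node_counter[0] += 1
        for gene in genes:
            gene.ancestors = dict(gene.ancestors)
            gene.ancestors[node_id] = gene.copy_id
        child_leaf_sets = [set(_tree_leaves(child)) for child in node]
        for i, li in enumerate(child_leaf_sets):
            for lj in child_leaf_sets[i + 1 :]:
                for a in li:
                    for b in lj:
                        lca[frozenset((a, b))] = node_id
        for child in node:
            child_genes: list[_Gene] = []
            for gene in genes:
                n_copies = 1 + int(rng.poisson(config.duplication_rate))
                for _ in range(n_copies):
                    residues = _mutate(
                        gene.residues, gene.motif_span, config.substitution_rate, rng
                    )
                    child_genes.append(
                        _Gene(new_copy_id(), residues, gene.motif_span, gene.ancestors)
                    )
            process(child, child_genes)

    if len(config.species_labels) == 1:
        leaf_genes[config.species_labels[0]] = root_genes
    else:
        process(tree, root_genes)

    # materialize records per species, in deterministic label order
    proteomes: dict[str, list[ProteinRecord]] = {}
    gene_meta: dict[str, _Gene] = {}
    carrier_ids: set[str] = set()
    for species in config.species_labels:
        genome_tag = species[:1].upper()
        records = []
        for k, gene in enumerate(leaf_genes.get(species, []), start=1):
            gid = f"{species}_g{k}"
            is_contig = bool(rng.random() < config.contig_fraction)
            if is_contig:
                gid = CONTIG_PREFIX + gid
            chrom = f"{int(rng.integers(1, 8))}{genome_tag}"
            arm = "S" if rng.random() < 0.5 else "L"
            pos = int(rng.integers(1, 1_000_000))
            records.append(
                ProteinRecord(
                    id=gid,
                    species=species,
                    residues=gene.residues,
                    chromosome=chrom,
                    arm=arm,
                    position=pos,
                    is_contig=is_contig,
                )
            )
            gene_meta[gid] = gene
            if gene.motif_span is not None:
                carrier_ids.add(gid)
        proteomes[species] = records

    truth_groups: dict[tuple[str, str], list[frozenset]] = {}
    labels = list(config.species_labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            node_id = lca.get(frozenset((a, b)))
            groups: dict[int, set[str]] = {}
            for species in (a, b):
                for rec in proteomes[species]:
                    gene = gene_meta[rec.id]
                    anc = (
                        gene.ancestors.get(node_id)
                        if node_id is not None
                        else gene.copy_id
                    )
                    if anc is not None:
                        groups.setdefault(anc, set()).add(rec.id)
            truth_groups[(a, b)] = [
                frozenset(members) for _anc, members in sorted(groups.items())
            ]
    return SyntheticCohort(
        proteomes=proteomes, truth_groups=truth_groups, truth_bzip_ids=carrier_ids
    )


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted per-gene heterosis modes for an expression panel.

    ``log2_excess`` is the planted deviation: the F1's log2 distance
    beyond the extreme parent for over-/under-dominance, and the log2
    separation between the two parents for every gene.
    """

    gene_ids: tuple[str, ...]
    modes: tuple[str, ...]
    log2_excess: tuple[float, ...]
    noise_sd: float = 0.2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.modes) != len(self.gene_ids) or len(self.log2_excess) != len(
            self.gene_ids
        ):
            raise ValueError("gene_ids, modes and log2_excess must align")
        valid = {MODE_OVER, MODE_UNDER, MODE_HIGH, MODE_LOW, MODE_ADDITIVE}
        bad = set(self.modes) - valid
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")
        if any(x <= 0 for x in self.log2_excess):
            raise ValueError("planted log2 excess values must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


def random_expression_truth(
    n_genes: int,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    log2_excess: float = 2.0,
    seed: int = 0,
    include_additive: bool = True,
) -> ExpressionTruth:
    """Uniformly sample planted modes for ``n_genes`` genes."""
    rng = np.random.default_rng(seed)
    modes_pool = [MODE_OVER, MODE_UNDER, MODE_HIGH, MODE_LOW]
    if include_additive:
        modes_pool.append(MODE_ADDITIVE)
    modes = tuple(modes_pool[i] for i in rng.integers(0, len(modes_pool), n_genes))
    return ExpressionTruth(
        gene_ids=tuple(f"gene{i + 1}" for i in range(n_genes)),
        modes=modes,
        log2_excess=tuple([log2_excess] * n_genes),
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        seed=seed,
    )


def simulate_expression_panel(
    truth: ExpressionTruth,
    genotypes: Sequence[str] = ("parent1", "parent2", "F1"),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate a replicated log2 expression panel with planted modes.

    ``genotypes`` are interpreted as (parent1, parent2, F1).  Returns
    the genes x samples log2 matrix and the sample-to-genotype map.
    Sample columns are ``{genotype}_r{i}``.
    """
    if len(genotypes) != 3:
        raise ValueError("exactly three genotype labels required (P1, P2, F1)")
    g_p1, g_p2, g_f1 = genotypes
    rng = np.random.default_rng(truth.seed)
    n = truth.n_replicates
    rows = {}
    for gid, mode, excess in zip(truth.gene_ids, truth.modes, truth.log2_excess):
        base = rng.uniform(4.0, 10.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mean_p1 = base
        mean_p2 = base + sign * excess
        hi, lo = max(mean_p1, mean_p2), min(mean_p1, mean_p2)
        if mode == MODE_OVER:
            mean_f1 = hi + excess
        elif mode == MODE_UNDER:
            mean_f1 = lo - excess
        elif mode == MODE_HIGH:
            mean_f1 = hi
        elif mode == MODE_LOW:
            mean_f1 = lo
        else:  # additive
            mean_f1 = 0.5 * (mean_p1 + mean_p2)
        values = []
        for mean in (mean_p1, mean_p2, mean_f1):
            values.extend(mean + truth.noise_sd * rng.standard_normal(n))
        rows[gid] = values
    columns = (
        [f"{g_p1}_r{i + 1}" for i in range(n)]
        + [f"{g_p2}_r{i + 1}" for i in range(n)]
        + [f"{g_f1}_r{i + 1}" for i in range(n)]
    )
    panel = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    sample_genotype = {
        col: col.rsplit("_r", 1)[0] for col in columns
    }
    return panel, sample_genotype


def simulate_ct_panel(
    fold_changes: Mapping[str, float],
    reference_gene: str = "actin",
    calibrator_sample: str = "control",
    treated_sample: str = "treated",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_ct: float = 20.0,
):
    """Construct a Ct table whose 2^-ddCt analysis recovers the folds.

    Per gene, the treated-condition mean Ct sits ``log2(fold)`` cycles
    below the calibrator's (after reference correction), so at
    ``noise_sd=0`` the recovery is exact.  Noise perturbs target-gene
    Cts only; the reference gene is the stable internal control.
    Raises on non-positive fold changes.
    """
    from .expression import CtTable

    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    samples = [f"{calibrator_sample}_r{i + 1}" for i in range(n_replicates)] + [
        f"{treated_sample}_r{i + 1}" for i in range(n_replicates)
    ]
    condition = {
        s: calibrator_sample if s.startswith(calibrator_sample) else treated_sample
        for s in samples
    }
    data = {}
    data[reference_gene] = [reference_ct] * (2 * n_replicates)
    for gene, fold in fold_changes.items():
        base = rng.uniform(22.0, 30.0)
        control = base + noise_sd * rng.standard_normal(n_replicates)
        treated = (
            base - np.log2(fold) + noise_sd * rng.standard_normal(n_replicates)
        )
        data[gene] = list(control) + list(treated)
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return CtTable(
        values=values,
        sample_condition=condition,
        reference_gene=reference_gene,
        calibrator=calibrator_sample,
    )
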