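"""Expression analysis: relative quantification, DE filtering, probe
mapping, responsiveness grouping and heterosis expression modes.

Relative qPCR quantification follows the 2^-ddCt method: for a target
gene, ddCt = (Ct_target - Ct_reference) in a condition minus the same
difference in the calibrator condition, and the fold change is
2^-ddCt.  Differential expression uses a per-gene two-sample Welch
t-test on log2 values with Benjamini-Hochberg adjustment; a gene passes
when both the raw and the adjusted p-value are below alpha.

Heterosis expression modes compare an F1 hybrid with its two inbred
parents: *over-dominance* (F1 significantly above both parents),
*under-dominance* (below both), *high-/low-parent dominance* (F1
indistinguishable from one parent and significantly different from the
other), and *unclassified* otherwise (e.g. significant against both
parents but lying between them, or no significant contrast at all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .orthology import (
    DEFAULT_SCHEME,
    NUCLEOTIDE_SCHEME,
    ScoringScheme,
    local_align_bitscore,
)

MODE_OVER = "over-dominance"
MODE_UNDER = "under-dominance"
MODE_HIGH = "high-parent dominance"
MODE_LOW = "low-parent dominance"
MODE_ADDITIVE = "additive"
MODE_UNCLASSIFIED = "unclassified"

NON_ADDITIVE_MODES = (MODE_OVER, MODE_UNDER, MODE_HIGH, MODE_LOW)


@dataclass
class CtTable:
    """Cycle-threshold values, genes x samples, with sample conditions.

    ``sample_condition`` maps each sample (column) to its condition;
    replicates of a condition share the label.  ``reference_gene`` is
    the internal control (e.g. wheat Actin) and ``calibrator`` the
    condition every fold change is expressed against (e.g. 0 h).
    """

    values: pd.DataFrame
    sample_condition: dict[str, str]
    reference_gene: str
    calibrator: str

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_condition)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.reference_gene not in self.values.index:
            raise ValueError(f"reference gene {self.reference_gene!r} absent")
        if self.calibrator not in set(self.sample_condition.values()):
            raise ValueError(f"calibrator condition {self.calibrator!r} absent")

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.sample_condition[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_condition[s] == condition]


@dataclass
class RelativeExpression:
    """2^-ddCt fold changes per gene and condition.

    ``folds`` uses replicate-mean Cts; ``replicate_folds`` keeps the
    per-sample values (each sample's dCt against the calibrator's mean
    dCt) for downstream replicate-level tests.
    """

    folds: pd.DataFrame
    replicate_folds: pd.DataFrame
    calibrator: str
    sample_condition: dict[str, str]


def delta_delta_ct(ct: CtTable) -> RelativeExpression:
    """Relative quantification by the 2^-ddCt method.

    Raises if the reference gene has a missing Ct in any sample.
    """
    ref = ct.values.loc[ct.reference_gene]
    if ref.isna().any():
        missing = list(ref[ref.isna()].index)
        raise ValueError(f"reference gene Ct missing in sample(s) {missing}")
    if not np.isfinite(ct.values.to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")

    dct = ct.values.sub(ref, axis="columns")  # per-sample dCt
    conditions = ct.conditions()
    mean_dct = pd.DataFrame(
        {c: dct[ct.samples_of(c)].mean(axis=1) for c in conditions}
    )
    ddct = mean_dct.sub(mean_dct[ct.calibrator], axis="index")
    folds = 2.0 ** (-ddct)
    replicate_ddct = dct.sub(mean_dct[ct.calibrator], axis="index")
    replicate_folds = 2.0 ** (-replicate_ddct)
    return RelativeExpression(
        folds=folds,
        replicate_folds=replicate_folds,
        calibrator=ct.calibrator,
        sample_condition=dict(ct.sample_condition),
    )


@dataclass(frozen=True)
class DEResult:
    gene: str
    direction: str  # "up" | "down"
    p_value: float
    adjusted_p: float
    passes: bool


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch p; degenerate zero-variance comparisons give 1."""
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return 1.0
    p = stats.ttest_ind(x, y, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def de_filter(
    log2_matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of ``group_a`` vs ``group_b`` (log2 values).

    Returns a frame with raw p, BH-adjusted p, direction ("up" if the
    mean of ``group_a`` exceeds that of ``group_b``) and the ``passes``
    flag: raw p < alpha AND adjusted p < alpha.  Genes where both
    groups have zero variance receive p = 1.  Each group needs at least
    two replicates.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    a = log2_matrix[list(group_a)].to_numpy(dtype=float)
    b = log2_matrix[list(group_b)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # degenerate zero-variance rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0.0) & (b.var(axis=1) == 0.0)
    pvals[degenerate | np.isnan(pvals)] = 1.0
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    frame = pd.DataFrame(
        {
            "direction": np.where(diff >= 0, "up", "down"),
            "p_value": pvals,
            "adjusted_p": adjusted,
        },
        index=log2_matrix.index,
    )
    frame["passes"] = (frame["p_value"] < alpha) & (frame["adjusted_p"] < alpha)
    return frame


def _translate_frames(nt: str) -> list[str]:
    from Bio.Seq import Seq

    frames = []
    for off in range(3):
        sub = nt[off:]
        sub = sub[: len(sub) - len(sub) % 3]
        if sub:
            frames.append(str(Seq(sub).translate()).replace("*", "X"))
    return frames


def evalue(bit_score: float, m: int, n: int, karlin_k: float) -> float:
    """Karlin-Altschul expect value ``K * m * n * 2^-bits``."""
    return karlin_k * m * n * 2.0 ** (-bit_score)


def map_probes_to_genes(
    probes: Mapping[str, str],
    cds: Mapping[str, str],
    proteins: Mapping[str, str],
    e_cds: float = 1e-5,
    e_protein: float = 1e-3,
    nt_scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
    aa_scheme: ScoringScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Map array probes to genes by a two-criterion E-value rule.

    A probe maps to a gene iff (1) its nucleotide alignment against the
    gene's CDS has E <= ``e_cds`` and (2) the best of its three forward
    translation frames aligned against the gene's protein has
    E <= ``e_protein``.  Probes mapping to several genes are reported
    for all of them and flagged ambiguous.
    """
    rows = []
    mapped_count: dict[str, int] = {p: 0 for p in probes}
    for probe_id, probe_seq in probes.items():
        frames = _translate_frames(probe_seq)
        for gene_id, cds_seq in cds.items():
            nt_pair = local_align_bitscore(
                probe_seq, cds_seq, nt_scheme, nucleotide=True
            )
            e_nt = evalue(
                nt_pair.bit_score, len(probe_seq), len(cds_seq), nt_scheme.karlin_k
            )
            prot = proteins[gene_id]
            e_aa = np.inf
            for frame in frames:
                aa_pair = local_align_bitscore(frame, prot, aa_scheme)
                e_aa = min(
                    e_aa,
                    evalue(aa_pair.bit_score, len(frame), len(prot), aa_scheme.karlin_k),
                )
            mapped = (e_nt <= e_cds) and (e_aa <= e_protein)
            if mapped:
                mapped_count[probe_id] += 1
            rows.append(
                {
                    "probe": probe_id,
                    "gene": gene_id,
                    "e_value_cds": e_nt,
                    "e_value_protein": e_aa,
                    "mapped": mapped,
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["ambiguous"] = frame["probe"].map(lambda p: mapped_count[p] > 1) & frame[
            "mapped"
        ]
    return frame


def responsiveness_class(
    course: Sequence[float],
    threshold: float = 10.0,
    band: float = 2.0,
) -> str:
    """Classify a fold-change time course as strong/weak/unresponsive.

    ``course`` holds relative expression values with the untreated
    reference first (value 1 by construction).  *strong*: some
    post-treatment fold exceeds ``threshold`` times the control;
    *weak*: responsive (max fold >= ``band`` or min fold <= 1/band)
    but not strong; *unresponsive* otherwise.
    """
    if len(course) == 0:
        raise ValueError("empty time course")
    post = np.asarray(course[1:], dtype=float)
    if post.size == 0:
        raise ValueError("time course has no post-treatment points")
    if post.max() > threshold:
        return "strong"
    if post.max() >= band or post.min() <= 1.0 / band:
        return "weak"
    return "unresponsive"


@dataclass(frozen=True)
class ModeCall:
    """Per-gene heterosis expression-mode call."""

    gene: str
    mode: str
    p_parent1: float
    p_parent2: float
    mid_parent_deviation_sign: int


def classify_expression_mode(
    f1: Sequence[float],
    parent1: Sequence[float],
    parent2: Sequence[float],
    alpha: float = 0.05,
    gene: str = "",
) -> ModeCall:
    """Classify the F1-vs-parents expression mode by Welch t-tests.

    Inputs are replicate-level expression values on a common scale
    (log2 folds by convention), at least two replicates per genotype.
    See the module docstring for the mode definitions.  When a
    dominance call is possible the nearer parent mean resolves high- vs
    low-parent dominance; an exact tie resolves toward the high parent
    iff the F1 mean is at or above the mid-parent value.
    """
    f1 = np.asarray(f1, dtype=float)
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    for name, arr in (("f1", f1), ("parent1", p1), ("parent2", p2)):
        if arr.size < 2:
            raise ValueError(f"{name} needs >= 2 replicates")

    if f1.var() == 0.0 and p1.var() == 0.0 and p2.var() == 0.0:
        # degenerate: no within-genotype variability, t-tests undefined
        warnings.warn(
            "zero-variance replicate triples: expression mode undetermined",
            stacklevel=2,
        )
        return ModeCall(gene, MODE_UNCLASSIFIED, 1.0, 1.0, 0)

    pv1 = _welch_p(f1, p1)
    pv2 = _welch_p(f1, p2)
    fm, m1, m2 = f1.mean(), p1.mean(), p2.mean()
    mid = 0.5 * (m1 + m2)
    dev_sign = int(np.sign(fm - mid))
    sig1, sig2 = pv1 < alpha, pv2 < alpha

    if sig1 and sig2:
        if fm > max(m1, m2):
            mode = MODE_OVER
        elif fm < min(m1, m2):
            mode = MODE_UNDER
        else:
            mode = MODE_UNCLASSIFIED
    elif sig1 or sig2:
        hi, lo = max(m1, m2), min(m1, m2)
        if abs(fm - hi) < abs(fm - lo):
            mode = MODE_HIGH
        elif abs(fm - hi) > abs(fm - lo):
            mode = MODE_LOW
        else:
            mode = MODE_HIGH if fm >= mid else MODE_LOW
    else:
        mode = MODE_UNCLASSIFIED
    return ModeCall(gene, mode, pv1, pv2, dev_sign)
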