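"""Pairwise nucleotide divergence, 99%-identity OTUs, closely related pairs.

Divergence between two ASVs is the number of mismatching aligned columns of
a global pairwise alignment (match +1, mismatch -1, gap open -4, gap extend
-1, terminal gaps free).  Internal gap columns count as mismatches,
terminal overhangs are ignored, and an N never matches anything.  ASVs are
clustered into OTUs by average-linkage (UPGMA) agglomeration on the
fractional distance, cut at 1 - identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

_ALPHABET = "ACGTN"


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -4.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # N matches nothing, not even another N
            matrix[a, b] = match if (a == b and a != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = "global"
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # terminal gaps free: ASVs from one primer set differ mainly by a few
    # bases of length at the ends
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class DivergenceMatrix:
    """Symmetric mismatch counts and per-pair alignment lengths."""

    mismatches: pd.DataFrame  # integer
    alignment_lengths: pd.DataFrame  # integer

    @property
    def ids(self) -> list[str]:
        return list(self.mismatches.index)

    def identity(self) -> pd.DataFrame:
        """Fractional identity = 1 - mismatches / alignment length."""
        frac = self.mismatches.to_numpy() / self.alignment_lengths.to_numpy()
        out = pd.DataFrame(1.0 - frac, index=self.mismatches.index,
                           columns=self.mismatches.columns)
        np.fill_diagonal(out.values, 1.0)
        return out

    def to_long(self) -> pd.DataFrame:
        """Long format: asv_a, asv_b, mismatches, aln_len, identity."""
        ids = self.ids
        rows = []
        mm = self.mismatches.to_numpy()
        al = self.alignment_lengths.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], int(mm[i, j]), int(al[i, j]),
                             1.0 - mm[i, j] / al[i, j]))
        return pd.DataFrame(
            rows, columns=["asv_a", "asv_b", "mismatches", "aln_len", "identity"]
        )


def _alignment_divergence(alignment) -> tuple[int, int]:
    """(mismatch count, alignment length) from one pairwise alignment.

    Aligned segments contribute their mismatching columns; internal gap
    columns count one mismatch each; overhangs before the first / after the
    last aligned segment are ignored.
    """
    a = alignment.target
    b = alignment.query
    seg_a, seg_b = alignment.aligned
    mism = 0
    cols = 0
    for k, ((sa, ea), (sb, eb)) in enumerate(zip(seg_a, seg_b)):
        xa = a[sa:ea]
        xb = b[sb:eb]
        for ca, cb in zip(xa, xb):
            cols += 1
            if ca != cb or ca == "N":
                mism += 1
        if k + 1 < len(seg_a):
            gap = (seg_a[k + 1][0] - ea) + (seg_b[k + 1][0] - eb)
            mism += gap
            cols += gap
    if cols == 0:
        # nothing aligns under the scoring (unrelated sequences): report
        # maximal divergence rather than an undefined 0/0 identity
        m = max(len(a), len(b))
        return m, m
    return mism, cols


def pairwise_divergence(sequences: dict[str, str]) -> DivergenceMatrix:
    """All-pairs nucleotide divergence of ASV sequences.

    For equal-length pairs the ungapped (Hamming) alignment is used when no
    gapped alignment can score higher under the configured scoring
    (verified via the aligner's optimal score), which keeps the common
    indel-free case fast and exact.
    """
    ids = list(sequences)
    for asv in ids:
        if len(sequences[asv]) == 0:
            raise ValueError(f"empty sequence for {asv!r}")
        seq = sequences[asv].upper()
        bad = set(seq) - set(_ALPHABET)
        if bad:
            raise ValueError(f"invalid symbols {sorted(bad)} in {asv!r}")
    aligner = _make_aligner()
    n = len(ids)
    mm = np.zeros((n, n), dtype=np.int64)
    al = np.zeros((n, n), dtype=np.int64)
    encoded = {a: np.frombuffer(sequences[a].upper().encode(), dtype=np.uint8)
               for a in ids}
    is_n = {a: encoded[a] == ord("N") for a in ids}
    for i in range(n):
        al[i, i] = len(sequences[ids[i]])
        for j in range(i + 1, n):
            sa, sb = sequences[ids[i]].upper(), sequences[ids[j]].upper()
            if len(sa) == len(sb):
                ham = int(((encoded[ids[i]] != encoded[ids[j]])
                           | is_n[ids[i]] | is_n[ids[j]]).sum())
                ungapped_score = len(sa) - 2 * ham
                if aligner.score(sa, sb) <= ungapped_score:
                    mm[i, j] = mm[j, i] = ham
                    al[i, j] = al[j, i] = len(sa)
                    continue
            best = aligner.align(sa, sb)[0]
            d, cols = _alignment_divergence(best)
            mm[i, j] = mm[j, i] = d
            al[i, j] = al[j, i] = cols
    return DivergenceMatrix(
        mismatches=pd.DataFrame(mm, index=ids, columns=ids),
        alignment_lengths=pd.DataFrame(al, index=ids, columns=ids),
    )


def cluster_otus(div: DivergenceMatrix, identity: float = 0.99,
                 linkage_method: str = "average") -> pd.Series:
    """UPGMA clustering of ASVs on fractional distance, cut at 1 - identity.

    Returns an ASV -> OTU label Series; labels are "OTU<k>" numbered by
    first appearance in the input order.
    """
    ids = div.ids
    if len(ids) == 1:
        return pd.Series({ids[0]: "OTU1"}, name="otu")
    dist = div.mismatches.to_numpy() / div.alignment_lengths.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    raw = fcluster(Z, t=1.0 - identity, criterion="distance")
    order: dict[int, int] = {}
    labels = []
    for lab in raw:
        labels.append(f"OTU{order.setdefault(lab, len(order) + 1)}")
    return pd.Series(labels, index=pd.Index(ids, name="asv"), name="otu")


def closely_related_pairs(
    div: DivergenceMatrix,
    taxonomy: pd.DataFrame,
    max_nt: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Within-genus ASV pairs at <= max_nt mismatches.

    Returns the pair table (asv_a, asv_b, genus, mismatches) and a per-genus
    count of ASVs participating in at least one such pair.
    """
    if "genus" not in taxonomy.columns:
        raise ValueError("taxonomy lacks a 'genus' column")
    genus = taxonomy["genus"]
    ids = [a for a in div.ids if a in genus.index]
    mm = div.mismatches
    rows = []
    participants: dict[str, set] = {}
    for gname, members in pd.Series(ids).groupby(
        genus.loc[ids].to_numpy()
    ):
        mem = members.tolist()
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                d = int(mm.loc[mem[i], mem[j]])
                if d <= max_nt:
                    rows.append((mem[i], mem[j], gname, d))
                    participants.setdefault(gname, set()).update(
                        (mem[i], mem[j])
                    )
    pairs = pd.DataFrame(rows, columns=["asv_a", "asv_b", "genus", "mismatches"])
    per_genus = pd.Series(
        {g: len(s) for g, s in participants.items()}, name="n_close_asvs",
        dtype=int,
    )
    return pairs, per_genus
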