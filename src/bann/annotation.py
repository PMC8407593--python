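"""SNP-set annotation: mapping SNPs to genes and intergenic regions.

The partially connected architecture of the network is entirely determined by
an :class:`AnnotationMask` — a binary J x G membership matrix connecting each
SNP (input unit) to the SNP-sets (hidden units) it belongs to.  SNP-sets are
genes (optionally expanded by a regulatory buffer, e.g. +/-500 kb) plus the
intergenic runs between consecutive annotated genes on each chromosome.

Conventions: gene intervals are held 1-based inclusive internally; BED input
(0-based, half-open) is converted on load.  SNP positions follow the VCF
convention (1-based).  Membership is inclusive at both interval ends.  Strand
is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "GeneInterval",
    "AnnotationMask",
    "load_gene_intervals",
    "build_annotation_mask",
    "validate_snp_map",
]

GENE = "gene"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneInterval:
    """A named gene span, 1-based inclusive coordinates."""

    gene_name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_name!r}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class AnnotationMask:
    """Binary SNP-to-SNP-set membership defining the network connectivity.

    Attributes
    ----------
    snp_ids : (J,) array of SNP identifiers, in genotype-column order.
    set_names : (G,) array of SNP-set names.
    membership : J x G sparse CSC boolean indicator.
    set_kind : (G,) array with entries ``"gene"`` or ``"intergenic"``.

    Invariants (checked by :meth:`validate`): every set has >= 2 member SNPs,
    every SNP belongs to >= 1 set.  A SNP may belong to several sets when
    gene annotations overlap.
    """

    snp_ids: np.ndarray
    set_names: np.ndarray
    membership: sparse.csc_matrix
    set_kind: np.ndarray
    set_bounds: pd.DataFrame = field(default=None, repr=False)

    @property
    def n_snps(self) -> int:
        return self.membership.shape[0]

    @property
    def n_sets(self) -> int:
        return self.membership.shape[1]

    def members(self, g: int) -> np.ndarray:
        """Row indices of SNPs belonging to set ``g``."""
        return self.membership.indices[
            self.membership.indptr[g] : self.membership.indptr[g + 1]
        ]

    def validate(self) -> None:
        col = np.asarray(self.membership.sum(axis=0)).ravel()
        row = np.asarray(self.membership.sum(axis=1)).ravel()
        if (col < 2).any():
            bad = self.set_names[col < 2]
            raise ValueError(f"SNP-sets with fewer than 2 members: {list(bad)}")
        if (row < 1).any():
            bad = self.snp_ids[row < 1]
            raise ValueError(f"SNPs assigned to no SNP-set: {list(bad)}")

    def to_long_frame(self) -> pd.DataFrame:
        """Two-column long-format table (snp_id, set_name) plus set_kind."""
        coo = self.membership.tocoo()
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids[coo.row],
                "set_name": self.set_names[coo.col],
                "set_kind": self.set_kind[coo.col],
            }
        ).sort_values(["set_name", "snp_id"], ignore_index=True)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, snp_ids) -> "AnnotationMask":
        snp_ids = np.asarray(snp_ids, dtype=object)
        idx = {s: i for i, s in enumerate(snp_ids)}
        set_names, set_codes = np.unique(frame["set_name"].to_numpy(), return_inverse=True)
        rows = np.array([idx[s] for s in frame["snp_id"]], dtype=np.int64)
        m = sparse.csc_matrix(
            (np.ones(len(frame), dtype=np.int8), (rows, set_codes)),
            shape=(len(snp_ids), len(set_names)),
        )
        if "set_kind" in frame.columns:
            kind_of = dict(zip(frame["set_name"], frame["set_kind"]))
            kinds = np.array([kind_of[n] for n in set_names], dtype=object)
        else:
            kinds = np.array([GENE] * len(set_names), dtype=object)
        mask = cls(snp_ids=snp_ids, set_names=set_names, membership=m, set_kind=kinds)
        mask.validate()
        return mask


def validate_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Check a SNP map table (snp_id, chromosome, position; 1-based)."""
    required = {"snp_id", "chromosome", "position"}
    missing = required - set(snp_map.columns)
    if missing:
        raise ValueError(f"SNP map missing columns: {sorted(missing)}")
    if snp_map["snp_id"].duplicated().any():
        dup = snp_map.loc[snp_map["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_ids: {dup[:10]}")
    if (snp_map["position"] <= 0).any():
        raise ValueError("SNP positions must be strictly positive (1-based)")
    return snp_map


def load_gene_intervals(path) -> list[GeneInterval]:
    """Read gene intervals from a BED file (chrom, start, end, name).

    BED coordinates (0-based, half-open) are converted to 1-based inclusive.
    Records sharing a name are merged by the union of their spans.  Returns
    intervals sorted by (chromosome, start).
    """
    records: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns, got {len(parts)}")
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: start ({start0}) >= end ({end0})")
            start1, end1 = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
            if name in records:
                prev = records[name]
                if prev[0] != chrom:
                    raise ValueError(
                        f"{path}:{lineno}: gene {name!r} appears on multiple chromosomes"
                    )
                prev[1] = min(prev[1], start1)
                prev[2] = max(prev[2], end1)
            else:
                records[name] = [chrom, start1, end1]
    if not records:
        logger.warning("no gene intervals found in %s", path)
        return []
    genes = [GeneInterval(n, c, s, e) for n, (c, s, e) in records.items()]
    genes.sort(key=lambda g: (g.chromosome, g.start, g.end))
    return genes


def _merge_spans(spans: list[tuple[int, int, str]]) -> list[tuple[int, int, str, str]]:
    """Merge overlapping/adjacent (start, end, name) spans.

    Returns merged blocks as (start, end, left_name, right_name) where the
    left/right names are those of the outermost genes of the block — the names
    used when labelling flanking intergenic runs.
    """
    spans = sorted(spans)
    merged: list[list] = []
    for s, e, name in spans:
        if merged and s <= merged[-1][1] + 1:
            if e > merged[-1][1]:
                merged[-1][1] = e
                merged[-1][3] = name
        else:
            merged.append([s, e, name, name])
    return [tuple(m) for m in merged]


def build_annotation_mask(
    snp_map: pd.DataFrame,
    genes: list[GeneInterval],
    buffer_bp: int = 0,
) -> AnnotationMask:
    """Assign every SNP to gene and/or intergenic SNP-sets.

    A SNP at position p belongs to gene g iff start-buffer <= p <= end+buffer
    (inclusive).  SNPs covered by no buffered gene are grouped, per chromosome,
    into maximal runs between consecutive annotated gene blocks, named
    ``GeneLeft-GeneRight`` (``chrStart-Gene`` / ``Gene-chrEnd`` at chromosome
    ends).  Gene sets with a single member SNP are dropped and their SNP folded
    into the surrounding intergenic run, so no SNP is silently discarded.

    Parameters
    ----------
    snp_map : DataFrame with columns snp_id, chromosome, position (1-based).
    genes : gene intervals (1-based inclusive); may be empty.
    buffer_bp : symmetric expansion of every gene span, in base pairs.
    """
    if buffer_bp < 0:
        raise ValueError("buffer_bp must be >= 0")
    snp_map = validate_snp_map(snp_map)
    if len(snp_map) == 0:
        raise ValueError("SNP map is empty")
    snp_ids = snp_map["snp_id"].to_numpy(dtype=object)
    chrom = snp_map["chromosome"].to_numpy(dtype=object)
    pos = snp_map["position"].to_numpy(dtype=np.int64)
    J = len(snp_ids)

    # --- gene membership via buffered interval trees -----------------------
    trees: dict[str, IntervalTree] = {}
    buffered: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        s = max(1, g.start - buffer_bp)
        e = g.end + buffer_bp
        buffered[g.gene_name] = (g.chromosome, s, e)
        trees.setdefault(g.chromosome, IntervalTree()).addi(s, e + 1, g.gene_name)

    gene_members: dict[str, list[int]] = {}
    for j in range(J):
        tree = trees.get(chrom[j])
        if tree is None:
            continue
        for iv in tree.at(int(pos[j])):
            gene_members.setdefault(iv.data, []).append(j)

    # Singleton gene sets are dropped here; their SNPs fall through to the
    # intergenic pass below (computed against retained genes only).
    retained = {name: idx for name, idx in gene_members.items() if len(idx) >= 2}
    dropped = sorted(set(gene_members) - set(retained))
    if dropped:
        logger.info("dropped %d singleton gene sets: %s", len(dropped), dropped[:10])

    covered = np.zeros(J, dtype=bool)
    for idx in retained.values():
        covered[idx] = True

    # --- intergenic runs between retained gene blocks ----------------------
    inter_sets: list[tuple[str, list[int]]] = []  # (name, member rows), ordered per chrom
    orphan_msgs: list[str] = []
    for c in sorted(set(chrom)):
        on_c = np.flatnonzero((chrom == c) & ~covered)
        if on_c.size == 0:
            continue
        spans = [
            (buffered[n][1], buffered[n][2], n)
            for n in retained
            if buffered[n][0] == c
        ]
        blocks = _merge_spans(spans)
        starts = np.array([b[0] for b in blocks], dtype=np.int64)
        runs: dict[int, list[int]] = {}
        for j in on_c:
            k = int(np.searchsorted(starts, pos[j], side="right"))  # gap index
            runs.setdefault(k, []).append(int(j))
        chrom_runs = []
        for k in sorted(runs):
            left = blocks[k - 1][3] if k > 0 else None
            right = blocks[k][2] if k < len(blocks) else None
            name = f"{left or 'chrStart'}-{right or 'chrEnd'}"
            if left is None and right is None:
                name = f"{c}.intergenic"
            chrom_runs.append([name, runs[k]])
        # fold singleton intergenic runs into the nearest neighbouring run
        while len(chrom_runs) > 1 and any(len(r[1]) < 2 for r in chrom_runs):
            i = next(i for i, r in enumerate(chrom_runs) if len(r[1]) < 2)
            p = pos[chrom_runs[i][1][0]]
            cand = []
            if i > 0:
                cand.append((min(abs(int(p) - int(pos[j])) for j in chrom_runs[i - 1][1]), i - 1))
            if i + 1 < len(chrom_runs):
                cand.append((min(abs(int(p) - int(pos[j])) for j in chrom_runs[i + 1][1]), i + 1))
            _, tgt = min(cand)
            lo, hi = sorted((i, tgt))
            merged_name = f"{chrom_runs[lo][0].split('-')[0]}-{chrom_runs[hi][0].split('-')[-1]}"
            chrom_runs[lo] = [merged_name, sorted(chrom_runs[lo][1] + chrom_runs[hi][1])]
            del chrom_runs[hi]
        for name, members in chrom_runs:
            if len(members) < 2:
                orphan_msgs.extend(str(snp_ids[j]) for j in members)
            else:
                inter_sets.append((name, members))
    if orphan_msgs:
        raise ValueError(
            "SNPs assignable to no SNP-set after singleton removal: "
            + ", ".join(orphan_msgs)
        )

    # --- assemble ----------------------------------------------------------
    names: list[str] = []
    kinds: list[str] = []
    bounds: list[tuple] = []
    rows: list[int] = []
    cols: list[int] = []
    for name in sorted(retained):
        col = len(names)
        names.append(name)
        kinds.append(GENE)
        c, s, e = buffered[name]
        bounds.append((name, c, s, e))
        for j in retained[name]:
            rows.append(j)
            cols.append(col)
    seen = set(names)
    for name, members in inter_sets:
        base, suffix = name, 1
        while name in seen:  # same flanking pair on another chromosome
            suffix += 1
            name = f"{base}.{suffix}"
        seen.add(name)
        col = len(names)
        names.append(name)
        kinds.append(INTERGENIC)
        mpos = pos[members]
        bounds.append((name, chrom[members[0]], int(mpos.min()), int(mpos.max())))
        for j in members:
            rows.append(j)
            cols.append(col)

    m = sparse.csc_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(J, len(names)),
    )
    mask = AnnotationMask(
        snp_ids=snp_ids,
        set_names=np.array(names, dtype=object),
        membership=m,
        set_kind=np.array(kinds, dtype=object),
        set_bounds=pd.DataFrame(bounds, columns=["set_name", "chromosome", "start", "end"]),
    )
    mask.validate()
    return mask
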