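"""Codon alignments, phylogenetic trees, and pairwise divergence statistics.

This module owns the two data containers everything else consumes — in-frame
codon alignments over the 61 sense codons of the universal genetic code, and
unrooted trees with optional foreground-branch flags (PAML-style ``#1``
labels) — together with the descriptive statistics used to assess a dataset
before model fitting: pairwise amino-acid identity and Nei–Gojobori (1986)
synonymous/nonsynonymous divergence with Jukes–Cantor correction, including
the saturation flagging that motivates caution at high kS.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "CODON_AA",
    "STOP_CODONS",
    "CodonAlignment",
    "PhyloTree",
    "PairwiseDivergence",
    "AlignmentError",
    "TreeError",
    "read_codon_alignment",
    "read_tree",
    "tree_from_newick",
    "pairwise_protein_identity",
    "ks_ng86",
    "divergence_table",
    "codon_state_mask",
    "translate_codon",
]

# ---------------------------------------------------------------------------
# Genetic code (universal / standard table), codons in T,C,A,G order as is
# conventional in the codon-model literature.
# ---------------------------------------------------------------------------

_NUCS = "TCAG"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.stop_codons))

CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in STOP_CODONS
)
assert len(CODONS) == 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
CODON_AA: tuple[str, ...] = tuple(_STANDARD_TABLE.forward_table[c] for c in CODONS)

_AMBIG = {k.upper(): set(v.upper()) for k, v in IUPACData.ambiguous_dna_values.items()}
_AMBIG["U"] = {"T"}
_GAP_CHARS = set("-.~?")


def translate_codon(codon: str) -> str:
    """Translate one codon; gaps -> '-', ambiguity -> 'X', stops -> '*'."""
    codon = codon.upper().replace("U", "T")
    if any(ch in _GAP_CHARS for ch in codon):
        return "-"
    if codon in STOP_CODONS:
        return "*"
    idx = CODON_INDEX.get(codon)
    if idx is not None:
        return CODON_AA[idx]
    return "X"


@lru_cache(maxsize=None)
def codon_state_mask(codon: str) -> np.ndarray:
    """Boolean mask over the 61 sense codons compatible with ``codon``.

    Gap-containing or fully ambiguous codons are missing data (all True);
    IUPAC ambiguity codes restrict to the compatible sense codons.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    if any(ch in _GAP_CHARS for ch in codon):
        return np.ones(61, dtype=bool)
    sets = []
    for ch in codon:
        if ch not in _AMBIG:
            raise ValueError(f"unknown nucleotide {ch!r} in codon {codon!r}")
        sets.append(_AMBIG[ch])
    mask = np.zeros(61, dtype=bool)
    for a in sets[0]:
        for b in sets[1]:
            for c in sets[2]:
                idx = CODON_INDEX.get(a + b + c)
                if idx is not None:
                    mask[idx] = True
    if not mask.any():
        # every compatible codon is a stop; treat as missing
        return np.ones(61, dtype=bool)
    return mask


def _is_missing(codon: str) -> bool:
    codon = codon.upper()
    return any(ch in _GAP_CHARS for ch in codon) or codon not in CODON_INDEX


# ---------------------------------------------------------------------------
# Codon alignment container
# ---------------------------------------------------------------------------


class AlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """An in-frame codon alignment.

    ``codons`` is a (n_taxa, n_codons) array of 3-letter strings; gaps and
    IUPAC ambiguity codes are preserved and treated as missing states by the
    likelihood machinery. Internal stop codons are invalid; a stop in the
    final column is replaced by a missing state (terminal stops carry no
    information under a sense-codon model).
    """

    taxa: list[str]
    codons: np.ndarray

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype="U3")
        if self.codons.ndim != 2:
            raise AlignmentError("codon matrix must be 2-D (taxa x sites)")
        if len(self.taxa) != self.codons.shape[0]:
            raise AlignmentError("taxa list does not match codon matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        n = self.codons.shape[1]
        for i, taxon in enumerate(self.taxa):
            for s in range(n):
                codon = str(self.codons[i, s]).upper().replace("U", "T")
                self.codons[i, s] = codon
                if codon in STOP_CODONS:
                    if s == n - 1:
                        self.codons[i, s] = "---"
                    else:
                        raise AlignmentError(
                            f"internal stop codon {codon} in taxon "
                            f"{taxon!r} at codon site {s + 1}"
                        )
                elif not _is_missing(codon):
                    codon_state_mask(codon)  # validates nucleotide letters

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, records: list[tuple[str, str]]) -> "CodonAlignment":
        """Build from ``(name, nucleotide_sequence)`` pairs."""
        if not records:
            raise AlignmentError("empty alignment")
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise AlignmentError("ragged alignment: sequences differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(
                f"sequence length {length} is not divisible by 3 (frame error)"
            )
        taxa = [name for name, _ in records]
        mat = np.array(
            [[seq[i : i + 3] for i in range(0, length, 3)] for _, seq in records],
            dtype="U3",
        )
        return cls(taxa=taxa, codons=mat)

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(self.codons[i])

    def translation(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(translate_codon(c) for c in self.codons[i])

    def site_column(self, site: int) -> list[str]:
        return [str(c) for c in self.codons[:, site]]

    # -- I/O ----------------------------------------------------------------

    def write(self, path: str | Path, format: str = "fasta") -> None:
        path = Path(path)
        if format == "fasta":
            with open(path, "w") as fh:
                for i, taxon in enumerate(self.taxa):
                    fh.write(f">{taxon}\n{''.join(self.codons[i])}\n")
        elif format == "phylip":
            with open(path, "w") as fh:
                fh.write(f" {self.n_taxa} {self.n_codons * 3}\n")
                for i, taxon in enumerate(self.taxa):
                    fh.write(f"{taxon}  {''.join(self.codons[i])}\n")
        else:
            raise ValueError(f"unknown alignment format {format!r}")


def _read_phylip_sequential(path: Path) -> list[tuple[str, str]]:
    """Relaxed sequential PHYLIP (whitespace-delimited names, PAML style)."""
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens.extend(line.split())
    if len(tokens) < 2:
        raise AlignmentError("malformed PHYLIP file: missing header")
    try:
        n_taxa, n_chars = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise AlignmentError("malformed PHYLIP header") from exc
    records: list[tuple[str, str]] = []
    pos = 2
    for _ in range(n_taxa):
        if pos >= len(tokens):
            raise AlignmentError("truncated PHYLIP file")
        name = tokens[pos]
        pos += 1
        chunks: list[str] = []
        got = 0
        while got < n_chars:
            if pos >= len(tokens):
                raise AlignmentError(f"truncated sequence for taxon {name!r}")
            chunk = tokens[pos]
            pos += 1
            chunks.append(chunk)
            got += len(chunk)
        seq = "".join(chunks)
        if len(seq) != n_chars:
            raise AlignmentError(
                f"sequence for {name!r} has {len(seq)} characters, expected {n_chars}"
            )
        records.append((name, seq))
    return records


def read_codon_alignment(path: str | Path, format: str = "fasta") -> CodonAlignment:
    """Read and validate an in-frame codon alignment (FASTA or sequential PHYLIP)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        records = _read_phylip_sequential(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    return CodonAlignment.from_sequences(records)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class TreeError(ValueError):
    pass


_HASH_RE = re.compile(r"#\s*(\d+)")
_HASH_LABEL_RE = re.compile(r"__HASH(\d+)__")


@dataclass
class PhyloTree:
    """An unrooted phylogeny stored as a rooted array representation.

    The root is an arbitrary internal node (a trifurcation for a fully
    resolved unrooted binary tree); under a reversible substitution model the
    likelihood does not depend on this choice. Each non-root node carries the
    length of, and the foreground flag on, the branch to its parent.
    """

    parent: np.ndarray  # (n_nodes,) int; -1 for the root
    lengths: np.ndarray  # (n_nodes,) float; branch above each node
    foreground: np.ndarray  # (n_nodes,) bool
    labels: list[str | None]  # leaf taxon labels; None for internal nodes

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if np.any(self.lengths[self.parent >= 0] < 0):
            raise TreeError("negative branch length")
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, u in enumerate(self.parent):
            if u >= 0:
                self._children[u].append(v)

    # -- structure ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def children(self, node: int) -> list[int]:
        return self._children[node]

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self._children[v]]

    @property
    def taxa(self) -> list[str]:
        return [self.labels[v] for v in self.leaves]  # type: ignore[misc]

    def is_leaf(self, node: int) -> bool:
        return not self._children[node]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self._children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    # -- derived trees ------------------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            foreground=self.foreground.copy(),
            labels=list(self.labels),
        )

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        t = self.copy()
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != t.lengths.shape:
            raise TreeError("branch-length vector has wrong shape")
        t.lengths = lengths
        return t

    def scaled(self, factor: float) -> "PhyloTree":
        if factor <= 0:
            raise TreeError("branch scale factor must be > 0")
        t = self.copy()
        t.lengths = t.lengths * factor
        return t

    def to_newick(self, mark_foreground: bool = True) -> str:
        def fmt(v: int) -> str:
            mark = "#1" if (mark_foreground and self.foreground[v]) else ""
            length = f":{self.lengths[v]:.6f}" if self.parent[v] >= 0 else ""
            if self.is_leaf(v):
                return f"{self.labels[v]}{mark}{length}"
            inner = ",".join(fmt(c) for c in self._children[v])
            return f"({inner}){mark}{length}"

        return fmt(self.root) + ";"


def tree_from_newick(text: str) -> PhyloTree:
    """Parse a Newick string; ``#k`` (k >= 1) branch labels mark foreground."""
    marked = _HASH_RE.sub(lambda m: f"__HASH{m.group(1)}__", text)
    dt = dendropy.Tree.get(
        data=marked,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def node_info(nd: dendropy.Node) -> tuple[str | None, bool]:
        raw = nd.taxon.label if nd.taxon is not None else nd.label
        flag = False
        label = raw
        if raw:
            m = _HASH_LABEL_RE.search(raw)
            if m:
                flag = int(m.group(1)) >= 1
                label = _HASH_LABEL_RE.sub("", raw).strip() or None
        return label, flag

    seed = dt.seed_node
    # collapse a bifurcating root so the tree is read as unrooted (2n-3 edges)
    kids = seed.child_nodes()
    if len(kids) == 2 and any(k.child_nodes() for k in kids):
        a, b = kids
        keep, move = (a, b) if a.child_nodes() else (b, a)
        length = (keep.edge.length or 0.0) + (move.edge.length or 0.0)
        _, fa = node_info(a)
        _, fb = node_info(b)
        seed.remove_child(keep)
        seed.remove_child(move)
        keep.add_child(move)
        move.edge.length = length
        if fa or fb:
            move.label = (move.label or "") + "__HASH1__"
        dt.seed_node = keep
        seed = keep
        seed.edge.length = None

    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    fg = np.zeros(len(nodes), dtype=bool)
    labels: list[str | None] = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        label, flag = node_info(nd)
        if not nd.child_nodes():
            if not label:
                raise TreeError("leaf without a label")
            labels[i] = label
        fg[i] = flag
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            length = nd.edge.length
            if length is None:
                length = 0.0
            if length < 0:
                raise TreeError(f"negative branch length {length}")
            lengths[i] = length
    tree = PhyloTree(parent=parent, lengths=lengths, foreground=fg, labels=labels)
    if len(set(tree.taxa)) != len(tree.taxa):
        raise TreeError("duplicate leaf labels")
    return tree


def read_tree(path: str | Path) -> PhyloTree:
    """Read a Newick tree file, honouring PAML-style ``#1`` foreground labels."""
    text = Path(path).read_text().strip()
    return tree_from_newick(text)


# ---------------------------------------------------------------------------
# Pairwise protein identity
# ---------------------------------------------------------------------------


def pairwise_protein_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical residues over aligned non-double-gap positions."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    matches = 0
    total = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        a_gap = a in _GAP_CHARS
        b_gap = b in _GAP_CHARS
        if a_gap and b_gap:
            continue
        total += 1
        if a == b and not a_gap:
            matches += 1
    if total == 0:
        raise ValueError("no aligned non-gap positions")
    return matches / total


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) synonymous / nonsynonymous divergence
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDivergence:
    """NG86 pairwise divergence with Jukes–Cantor correction.

    ``ks``/``ka`` are NaN when the proportion of differences exceeds the JC
    correctable range (``saturated``) or when no comparable sites exist
    (``undefined``).
    """

    taxon_a: str
    taxon_b: str
    ks: float
    ka: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated_s: bool = False
    saturated_n: bool = False
    undefined: bool = False

    @property
    def saturated(self) -> bool:
        return self.saturated_s or self.saturated_n


@lru_cache(maxsize=None)
def _codon_syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon: per position, the fraction of
    the three single-nucleotide changes that are synonymous (changes to stop
    codons count as nonsynonymous, the standard NG86 convention)."""
    total = 0.0
    aa = CODON_AA[CODON_INDEX[codon]]
    for pos in range(3):
        syn = 0
        for nuc in "TCAG":
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1 :]
            if mut not in STOP_CODONS and CODON_AA[CODON_INDEX[mut]] == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pair_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two sense
    codons over all minimal mutational pathways, excluding pathways through
    stop codons (equal weights, standard NG86)."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        # all pathways blocked by stops (possible for distant codon pairs):
        # count every step, classifying steps into/through stops as nonsynonymous
        for order in itertools.permutations(diff_pos):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    syn = 0.0
    nonsyn = 0.0
    for steps in paths:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                nonsyn += 1
            elif CODON_AA[CODON_INDEX[a]] == CODON_AA[CODON_INDEX[b]]:
                syn += 1
            else:
                nonsyn += 1
    n = len(paths)
    return syn / n, nonsyn / n


_NG86_TABLES: dict[str, np.ndarray] = {}


def _ng86_tables() -> dict[str, np.ndarray]:
    """Precomputed per-codon site counts and per-pair pathway difference counts."""
    if not _NG86_TABLES:
        s_sites = np.array([_codon_syn_sites(c) for c in CODONS])
        sd = np.zeros((61, 61))
        nd = np.zeros((61, 61))
        for i, ci in enumerate(CODONS):
            for j, cj in enumerate(CODONS):
                if i < j:
                    s, n = _pair_path_counts(ci, cj)
                    sd[i, j] = sd[j, i] = s
                    nd[i, j] = nd[j, i] = n
        _NG86_TABLES["s_sites"] = s_sites
        _NG86_TABLES["sd"] = sd
        _NG86_TABLES["nd"] = nd
    return _NG86_TABLES


def _jc_correct(p: float) -> tuple[float, bool]:
    if p < 0.75:
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False
    return float("nan"), True


def _codon_list(seq) -> list[str]:
    if isinstance(seq, str):
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise AlignmentError("sequence length not divisible by 3")
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return [str(c).upper() for c in seq]


def ks_ng86(seq_a, seq_b, taxon_a: str = "a", taxon_b: str = "b") -> PairwiseDivergence:
    """NG86 pairwise synonymous/nonsynonymous divergence with JC correction.

    Accepts nucleotide strings or codon lists of equal length. Codon columns
    where either sequence has a gap/ambiguity are skipped (pairwise deletion).
    """
    codons_a = _codon_list(seq_a)
    codons_b = _codon_list(seq_b)
    if len(codons_a) != len(codons_b):
        raise AlignmentError("sequences must have equal codon length")
    tables = _ng86_tables()
    s_sites_tab, sd_tab, nd_tab = tables["s_sites"], tables["sd"], tables["nd"]
    ia, ib = [], []
    for ca, cb in zip(codons_a, codons_b):
        xa = CODON_INDEX.get(ca)
        xb = CODON_INDEX.get(cb)
        if xa is None or xb is None:
            continue  # gap/ambiguity/stop: pairwise deletion
        ia.append(xa)
        ib.append(xb)
    n_comp = len(ia)
    if n_comp == 0:
        return PairwiseDivergence(
            taxon_a, taxon_b, float("nan"), float("nan"), 0, 0, 0, 0, undefined=True
        )
    ia_arr = np.array(ia)
    ib_arr = np.array(ib)
    s_sites = 0.5 * (s_sites_tab[ia_arr].sum() + s_sites_tab[ib_arr].sum())
    n_sites = 3.0 * n_comp - s_sites
    sd = sd_tab[ia_arr, ib_arr].sum()
    nd = nd_tab[ia_arr, ib_arr].sum()
    if s_sites <= 0:
        return PairwiseDivergence(
            taxon_a, taxon_b, float("nan"), float("nan"),
            s_sites, n_sites, sd, nd, undefined=True,
        )
    ps = sd / s_sites
    pn = nd / n_sites
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    return PairwiseDivergence(
        taxon_a, taxon_b, ks, ka, s_sites, n_sites, sd, nd,
        saturated_s=sat_s, saturated_n=sat_n,
    )


def divergence_table(alignment: CodonAlignment) -> pd.DataFrame:
    """All-pairs NG86 divergence as a tidy table (one row per unordered pair)."""
    rows = []
    for i, j in itertools.combinations(range(alignment.n_taxa), 2):
        d = ks_ng86(
            alignment.codons[i],
            alignment.codons[j],
            taxon_a=alignment.taxa[i],
            taxon_b=alignment.taxa[j],
        )
        rows.append(
            {
                "taxon_a": d.taxon_a,
                "taxon_b": d.taxon_b,
                "ks": d.ks,
                "ka": d.ka,
                "syn_sites": d.syn_sites,
                "nonsyn_sites": d.nonsyn_sites,
                "saturated": d.saturated,
                "undefined": d.undefined,
            }
        )
    return pd.DataFrame(rows)
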