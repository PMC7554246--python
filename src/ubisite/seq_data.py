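"""Sequence and site-annotation handling.

Reads FASTA proteins and lysine-site tables, extracts fixed-length
lysine-centred peptide fragments (X-padded at the termini), reduces
redundancy by greedy identity clustering, and builds balanced,
reproducible train/test splits.

Coordinate convention: site annotations and ``center_position`` are 1-based
(as in UniProt feature tables); all internal array indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: Canonical order of the 20 standard amino acids (alphabetical one-letter).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Pseudo-residue used for out-of-protein padding and non-standard symbols.
PAD_SYMBOL = "X"
#: Full 21-symbol alphabet after normalization.
ALPHABET = AA_ALPHABET + PAD_SYMBOL

_STANDARD = frozenset(AA_ALPHABET)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

# uint8 codes: residue -> 0..19, X -> 20
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class ProteinRecord:
    """A protein sequence over the 21-symbol normalized alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: symbols {sorted(bad)} outside the "
                f"21-letter alphabet; normalize first (see normalize_sequence)"
            )


@dataclass
class SiteFragment:
    """A window-length peptide centred on a lysine.

    ``center_position`` is the 1-based index of the central K in the parent
    protein.  Flank positions beyond the protein termini hold the pad
    symbol X.
    """

    protein_id: str
    center_position: int
    sequence: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def window(self) -> int:
        return len(self.sequence)


@dataclass
class FragmentDataset:
    """A labelled collection of site fragments."""

    fragments: list[SiteFragment]
    provenance: str = ""

    @property
    def n_positive(self) -> int:
        return sum(1 for f in self.fragments if f.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for f in self.fragments if f.label == NEGATIVE)

    def __len__(self) -> int:
        return len(self.fragments)

    def labels(self) -> np.ndarray:
        """0/1 array over the labelled fragments (positive = 1)."""
        return np.array(
            [1 if f.label == POSITIVE else 0 for f in self.fragments], dtype=np.int64
        )

    def subset(self, indices) -> "FragmentDataset":
        return FragmentDataset(
            [self.fragments[i] for i in indices], provenance=self.provenance
        )


@dataclass
class DatasetSplit:
    train: FragmentDataset
    test: FragmentDataset
    seed: int = 0


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard residues (B, J, O, U, Z, \\*, -, ...) to X."""
    seq = seq.upper()
    out = []
    replaced = set()
    for ch in seq:
        if ch in _STANDARD or ch == PAD_SYMBOL:
            out.append(ch)
        else:
            replaced.add(ch)
            out.append(PAD_SYMBOL)
    if replaced:
        warnings.warn(
            f"record {record_id!r}: non-standard residues "
            f"{sorted(replaced)} mapped to {PAD_SYMBOL}",
            stacklevel=2,
        )
    return "".join(out)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into normalized :class:`ProteinRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, seq, rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_sites_tsv(path) -> dict[str, set[int]]:
    """Read a site table (``protein_id<TAB>position``, one header line)."""
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty sites table {path}")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'protein_id<TAB>position'")
            sites.setdefault(parts[0], set()).add(int(parts[1]))
    return sites


def write_sites_tsv(sites: dict[str, set[int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\n")
        for pid in sites:
            for pos in sorted(sites[pid]):
                fh.write(f"{pid}\t{pos}\n")


def extract_fragments(
    protein: ProteinRecord,
    sites: set[int],
    window: int = 31,
) -> list[SiteFragment]:
    """Extract one fragment per lysine of ``protein``.

    Lysines at 1-based positions listed in ``sites`` become positive
    fragments, all other lysines negative ones.  Each fragment carries
    exactly ``(window - 1) // 2`` residues on either side of the central K,
    with out-of-protein flanks filled with the pad symbol X.

    Listed positions that do not hold K raise a warning and are skipped.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    half = (window - 1) // 2
    seq = protein.sequence
    for pos in sorted(sites):
        if pos < 1 or pos > len(seq) or seq[pos - 1] != "K":
            warnings.warn(
                f"protein {protein.id!r}: annotated site {pos} does not hold K "
                f"(annotation mismatch); skipped",
                stacklevel=2,
            )
    padded = PAD_SYMBOL * half + seq + PAD_SYMBOL * half
    fragments = []
    for idx, res in enumerate(seq):
        if res != "K":
            continue
        pos = idx + 1
        frag_seq = padded[idx : idx + window]
        label = POSITIVE if pos in sites else NEGATIVE
        fragments.append(SiteFragment(protein.id, pos, frag_seq, label))
    return fragments


def encode_sequences(sequences) -> np.ndarray:
    """Encode equal-length sequences as a uint8 matrix (A..Y -> 0..19, X -> 20)."""
    n = len(sequences)
    if n == 0:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(sequences[0])
    out = np.empty((n, length), dtype=np.uint8)
    for i, s in enumerate(sequences):
        if len(s) != length:
            raise ValueError("sequences must have uniform length")
        out[i] = [_CODE[c] for c in s]
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of aligned columns with identical residues; X never matches."""
    if len(a) != len(b):
        raise ValueError("pairwise_identity expects equal-length sequences")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != PAD_SYMBOL)
    return matches / len(a)


def cluster_reduce(
    fragments: list[SiteFragment], identity_threshold: float = 0.30
) -> list[SiteFragment]:
    """Greedy incremental identity clustering; returns cluster representatives.

    Fragments are processed in input order; a fragment joins the first
    cluster whose representative (founder) shares pairwise identity >= the
    threshold, otherwise it founds a new cluster.  For equal-length
    ungapped fragments identity is the Hamming fraction of identical
    columns; the pad symbol X never counts as a match.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    if not fragments:
        return []
    lengths = {f.window for f in fragments}
    if len(lengths) != 1:
        raise ValueError(f"mixed fragment lengths {sorted(lengths)}")
    length = lengths.pop()
    codes = encode_sequences([f.sequence for f in fragments])
    pad_code = _CODE[PAD_SYMBOL]

    rep_codes = np.empty((0, length), dtype=np.uint8)
    representatives: list[SiteFragment] = []
    for i, frag in enumerate(fragments):
        if len(representatives):
            row = codes[i]
            matches = ((rep_codes == row) & (row != pad_code)).sum(axis=1)
            if (matches / length >= identity_threshold).any():
                continue
        representatives.append(frag)
        rep_codes = np.vstack([rep_codes, codes[i][None, :]])
    return representatives


def balance_and_split(
    positives: list[SiteFragment],
    negatives: list[SiteFragment],
    test_size: int,
    seed: int = 0,
) -> DatasetSplit:
    """Balance classes by subsampling negatives, then hold out a stratified test set.

    Negatives are subsampled without replacement to ``len(positives)``; the
    held-out test set contains ``test_size`` fragments split as evenly as
    possible between the classes.  Fully reproducible from ``seed``.
    """
    n_pos = len(positives)
    if len(negatives) < n_pos:
        raise ValueError(
            f"need at least as many negatives ({len(negatives)}) as positives ({n_pos})"
        )
    total = 2 * n_pos
    if test_size >= total:
        raise ValueError(f"test_size {test_size} >= balanced total {total}")
    if test_size < 0:
        raise ValueError("test_size must be non-negative")
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(negatives), size=n_pos, replace=False)
    kept_neg = [negatives[i] for i in neg_idx]

    n_test_pos = test_size // 2
    n_test_neg = test_size - n_test_pos
    pos_perm = rng.permutation(n_pos)
    neg_perm = rng.permutation(n_pos)
    test = [positives[i] for i in pos_perm[:n_test_pos]] + [
        kept_neg[i] for i in neg_perm[:n_test_neg]
    ]
    train = [positives[i] for i in pos_perm[n_test_pos:]] + [
        kept_neg[i] for i in neg_perm[n_test_neg:]
    ]
    prov = f"balance_and_split(seed={seed}, test_size={test_size}, n_pos={n_pos})"
    return DatasetSplit(
        train=FragmentDataset(train, provenance=prov),
        test=FragmentDataset(test, provenance=prov),
        seed=seed,
    )


def write_dataset_tsv(dataset: FragmentDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter_position\tsequence\tlabel\n")
        for f in dataset.fragments:
            fh.write(f"{f.protein_id}\t{f.center_position}\t{f.sequence}\t{f.label}\n")


def read_dataset_tsv(path) -> FragmentDataset:
    fragments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "center_position", "sequence", "label"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, pos, seq, label = line.split("\t")
            fragments.append(SiteFragment(pid, int(pos), seq, label))
    return FragmentDataset(fragments, provenance=f"read_dataset_tsv({path})")
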