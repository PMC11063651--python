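"""Readers and writers for sequences, alignments, substitution matrices, and
a persistent embedding cache.

Sequences are plain uppercase strings over the 20 standard amino-acid letters
plus the ambiguity codes B, Z, X, U, O.  Gapped strings use ``-`` as the gap
character; ``.`` (common in conserved-domain exports) is normalized to ``-``
on input.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import h5py
import numpy as np
from Bio import AlignIO, SeqIO

STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"
AMBIGUITY = "BZXUO"
RESIDUE_ALPHABET = STANDARD_AA + AMBIGUITY
GAP = "-"


class FormatError(ValueError):
    """Raised for malformed sequence / alignment / matrix input."""


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence.  Positions are 1-based: ``seq[i]``
    with ``1 <= i <= len(seq)`` returns the i-th residue."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise FormatError(f"sequence {self.id!r} is empty")
        for ch in self.residues:
            if ch not in RESIDUE_ALPHABET:
                raise FormatError(
                    f"sequence {self.id!r} contains illegal character {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} out of range 1..{len(self.residues)}")
        return self.residues[i - 1]


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution matrix (e.g. BLOSUM45)."""

    name: str
    scores: dict  # frozen mapping (a, b) -> float, both orders present

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(
                f"pair ({a!r}, {b!r}) not covered by matrix {self.name}"
            ) from None

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.scores

    @property
    def letters(self) -> str:
        seen = []
        for a, _ in self.scores:
            if a not in seen:
                seen.append(a)
        return "".join(seen)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A pairwise alignment: two equal-length gapped strings with no column
    gapped in both rows.  De-gapping row 1 recovers P, row 2 recovers Q."""

    p_aligned: str
    q_aligned: str

    def __post_init__(self) -> None:
        if len(self.p_aligned) != len(self.q_aligned):
            raise FormatError(
                "alignment rows differ in length: "
                f"{len(self.p_aligned)} vs {len(self.q_aligned)}"
            )
        for k, (a, b) in enumerate(zip(self.p_aligned, self.q_aligned), start=1):
            if a == GAP and b == GAP:
                raise FormatError(f"column {k} is gapped in both rows")

    def __len__(self) -> int:
        return len(self.p_aligned)

    @property
    def p(self) -> str:
        return self.p_aligned.replace(GAP, "")

    @property
    def q(self) -> str:
        return self.q_aligned.replace(GAP, "")


@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment: k rows of identical gapped length."""

    rows: tuple  # of (id, gapped string)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("an MSA needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            bad = [rid for rid, s in self.rows]
            raise FormatError(f"rows have unequal lengths: {bad}")

    @property
    def alignment_length(self) -> int:
        return len(self.rows[0][1])

    def __len__(self) -> int:
        return len(self.rows)

    def sequence(self, i: int) -> ProteinSequence:
        """De-gapped row i (0-based) as a ProteinSequence."""
        rid, gapped = self.rows[i]
        return ProteinSequence(rid, gapped.replace(GAP, ""))


def _dedup_ids(ids: list) -> list:
    seen: dict = {}
    out = []
    for rid in ids:
        if rid in seen:
            seen[rid] += 1
            out.append(f"{rid}.{seen[rid]}")
        else:
            seen[rid] = 0
            out.append(rid)
    return out


def _normalize_residues(raw: str, rid: str) -> str:
    s = "".join(raw.split()).upper().replace("*", "")
    if not s:
        raise FormatError(f"record {rid!r} has an empty sequence")
    for ch in s:
        if ch not in RESIDUE_ALPHABET:
            raise FormatError(f"record {rid!r} contains illegal character {ch!r}")
    return s


def read_fasta(source) -> list:
    """Parse FASTA text into ProteinSequence objects (order preserved).

    ``source`` is a text stream or a string of FASTA content.  Residues are
    uppercased, whitespace is joined, ``*`` stop symbols are stripped, and
    duplicate ids are deduplicated by suffixing.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise FormatError("no FASTA records found")
    ids = _dedup_ids([r.id for r in records])
    return [
        ProteinSequence(rid, _normalize_residues(str(r.seq), rid))
        for rid, r in zip(ids, records)
    ]


def read_msa(source, format: str = "aligned-fasta") -> MSA:
    """Read an MSA from aligned FASTA or CLUSTAL text.

    Both ``.`` and ``-`` gap characters are normalized to ``-``.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise FormatError(f"unknown MSA format {format!r}")
    if fmt == "fasta":
        records = list(SeqIO.parse(source, "fasta"))
    else:
        records = list(AlignIO.read(source, "clustal"))
    if len(records) < 2:
        raise FormatError(f"MSA needs at least 2 rows, got {len(records)}")
    ids = _dedup_ids([r.id for r in records])
    rows = []
    for rid, rec in zip(ids, records):
        gapped = "".join(str(rec.seq).split()).upper().replace(".", GAP)
        for ch in gapped:
            if ch != GAP and ch not in RESIDUE_ALPHABET:
                raise FormatError(f"row {rid!r} contains illegal character {ch!r}")
        rows.append((rid, gapped))
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        bad = [rid for rid, s in rows if len(s) != len(rows[0][1])]
        raise FormatError(f"rows with lengths differing from the first: {bad}")
    return MSA(tuple(rows))


def read_substitution_matrix(source, name: str = "matrix") -> SubstitutionMatrix:
    """Parse an NCBI-style substitution matrix (``#`` comments, header row of
    column letters, labeled score rows).  Symmetry and coverage of the 20
    standard residues are validated."""
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = [ln for ln in source if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise FormatError("empty matrix file")
    columns = lines[0].split()
    scores: dict = {}
    row_letters = []
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        vals = parts[1:]
        if len(vals) != len(columns):
            raise FormatError(
                f"row {row!r} has {len(vals)} entries, expected {len(columns)}"
            )
        row_letters.append(row)
        for col, v in zip(columns, vals):
            scores[(row, col)] = float(v)
    for a in row_letters:
        for b in row_letters:
            if (a, b) in scores and (b, a) in scores:
                if scores[(a, b)] != scores[(b, a)]:
                    raise FormatError(
                        f"asymmetric entries: ({a},{b})={scores[(a, b)]} "
                        f"but ({b},{a})={scores[(b, a)]}"
                    )
    missing = [a for a in STANDARD_AA if (a, a) not in scores]
    if missing:
        raise FormatError(f"matrix lacks standard residues: {missing}")
    return SubstitutionMatrix(name, scores)


_BUILTIN_MATRICES = ("BLOSUM45", "BLOSUM50", "BLOSUM62", "BLOSUM80", "BLOSUM90")


def load_blosum(name: str) -> SubstitutionMatrix:
    """Load one of the bundled NCBI BLOSUM matrices by name (e.g. BLOSUM45)."""
    name = name.upper()
    if name not in _BUILTIN_MATRICES:
        raise KeyError(
            f"unknown matrix {name!r}; available: {', '.join(_BUILTIN_MATRICES)}"
        )
    text = resources.files("embalign.data").joinpath(f"{name}.txt").read_text()
    return read_substitution_matrix(text, name=name)


def write_alignment(alignment: PairwiseAlignment, ids=("p", "q")) -> str:
    """Serialize a pairwise alignment as two-record aligned FASTA.  The output
    round-trips through :func:`read_msa`."""
    return f">{ids[0]}\n{alignment.p_aligned}\n>{ids[1]}\n{alignment.q_aligned}\n"


# ---------------------------------------------------------------------------
# Embedding cache

class EmbeddingCache:
    """Persistent on-disk store of per-residue embedding matrices, keyed by
    (model name, sequence id).  A SHA-256 of the residue string is stored with
    each entry so a changed sequence under a reused id is detected."""

    def __init__(self, path):
        self.path = str(path)

    @staticmethod
    def _digest(residues: str) -> str:
        return hashlib.sha256(residues.encode()).hexdigest()

    def put(self, model_name: str, seq_id: str, residues: str, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        if values.shape[0] != len(residues):
            raise ValueError(
                f"matrix has {values.shape[0]} rows for a sequence of "
                f"length {len(residues)}"
            )
        with h5py.File(self.path, "a") as f:
            grp = f.require_group(model_name)
            if seq_id in grp:
                del grp[seq_id]
            ds = grp.create_dataset(seq_id, data=values)
            ds.attrs["sha256"] = self._digest(residues)

    def get(self, model_name: str, seq_id: str, residues: str):
        """Return the cached matrix, or None if absent."""
        try:
            with h5py.File(self.path, "r") as f:
                if model_name not in f or seq_id not in f[model_name]:
                    return None
                ds = f[model_name][seq_id]
                if ds.attrs.get("sha256") != self._digest(residues):
                    raise ValueError(
                        f"cache entry ({model_name}, {seq_id}) was stored for a "
                        "different residue string; refusing stale entry"
                    )
                return np.asarray(ds[...], dtype=np.float64)
        except FileNotFoundError:
            return None
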