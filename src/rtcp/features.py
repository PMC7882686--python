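"""Feature extraction: reduced tripeptide composition (RTC), the 20-dim
sigmoid-averaged PSSM summary, their concatenation (RTCP), PCA reduction,
and plain amino-acid composition.

The composite RTCP descriptor of a protein is::

    RTCP = [ RTC (K^3 dims) | PSSM-feature (20 dims) ]

where RTC is the normalized count of overlapping length-3 words of the
reduced-alphabet sequence and the PSSM feature averages the logistic
squashing 1/(1+exp(-a)) of PSI-BLAST log-odds scores down each of the 20
target-residue columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .alphabets import ReducedAlphabet, sanitize_sequence

#: PSI-BLAST PSSM column order for the 20 target residues.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWVY"

#: Alphabetical order used by amino_acid_composition.
AAC_COLUMNS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PSSMatrix:
    """Per-protein position-specific scoring matrix.

    ``scores`` is L x 20 (row = sequence position, column = target residue in
    PSI-BLAST order ARNDCQEGHILKMFPSTWVY), holding the log-odds block of the
    ASCII profile.
    """

    protein_id: str
    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got {scores.shape}")
        if scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if scores.shape[0] != len(self.residues):
            raise ValueError(
                f"{scores.shape[0]} score rows but {len(self.residues)} residues"
            )


@dataclass(frozen=True)
class FeatureVector:
    """A named, schema-carrying feature row for one protein."""

    protein_id: str
    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.schema):
            raise ValueError("values and schema lengths differ")

    def __len__(self) -> int:
        return len(self.values)


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed; names the line."""


def parse_pssm_ascii(text: str, protein_id: str = "") -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` profile.

    The layout is: header lines, a column-label line carrying 40 single
    letters (log-odds block then weighted-percentage block), then one row per
    residue starting with its position index and residue letter followed by
    at least 20 integer scores. Only the first 20 numeric columns (the
    log-odds block) are kept.
    """
    residues: list[str] = []
    rows: list[list[float]] = []
    in_body = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not in_body:
            toks = stripped.split()
            # the column-label line is the first line made only of residue letters
            if len(toks) >= 20 and all(t in PSSM_COLUMNS and len(t) == 1 for t in toks):
                in_body = True
            continue
        if not stripped:
            break  # blank line ends the body; footer statistics follow
        toks = stripped.split()
        if not toks[0].isdigit():
            break
        if len(toks) < 22:
            raise PSSMParseError(
                f"line {lineno}: expected position, residue and >=20 scores, "
                f"got {len(toks)} fields"
            )
        residue = toks[1]
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score ({exc})") from exc
        residues.append(residue)
        rows.append(scores)
    if not rows:
        raise PSSMParseError("no PSSM data rows found (empty or malformed body)")
    return PSSMatrix(protein_id, "".join(residues), np.array(rows))


def read_pssm(path: str | Path, protein_id: str | None = None) -> PSSMatrix:
    """Read an ASCII PSSM file; the protein id defaults to the file stem."""
    path = Path(path)
    return parse_pssm_ascii(path.read_text(), protein_id or path.stem)


def sigmoid_scale(a):
    """Squash a signed substitution score into (0, 1) via 1/(1+exp(-a))."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out if out.ndim else float(out)


def pssm_feature(m: PSSMatrix) -> FeatureVector:
    """Average the sigmoid-scaled scores down each of the 20 columns.

    Every component lies strictly in (0, 1); the result is independent of the
    ordering of rows (positions).
    """
    values = sigmoid_scale(m.scores).mean(axis=0)
    schema = tuple(f"pssm_{c}" for c in PSSM_COLUMNS)
    return FeatureVector(m.protein_id, values, schema)


def tripeptide_labels(k: int) -> tuple[str, ...]:
    """Lexicographic labels '0-0-0' ... '(k-1)-(k-1)-(k-1)' of the K^3 words."""
    return tuple(
        f"{x}-{y}-{z}" for x, y, z in itertools.product(range(k), repeat=3)
    )


def tripeptide_composition(
    reduced: list[int] | np.ndarray, k: int, protein_id: str = ""
) -> FeatureVector:
    """Frequency vector of overlapping length-3 words of a reduced sequence.

    Coordinate (x, y, z) sits at flat index x*k^2 + y*k + z and holds the
    window count divided by L-2, so the vector is a probability distribution
    over the K^3 possible reduced tripeptides.
    """
    reduced = np.asarray(reduced, dtype=np.int64)
    n = len(reduced)
    if n < 3:
        raise ValueError(f"sequence of reduced length {n} has no tripeptide window")
    if reduced.min() < 0 or reduced.max() >= k:
        raise ValueError("reduced symbols out of range for alphabet size")
    flat = reduced[:-2] * k * k + reduced[1:-1] * k + reduced[2:]
    counts = np.bincount(flat, minlength=k**3).astype(float)
    return FeatureVector(protein_id, counts / (n - 2), tripeptide_labels(k))


def assemble_rtcp(rtc: FeatureVector, pssm_f: FeatureVector) -> FeatureVector:
    """Concatenate the RTC block and the 20-dim PSSM feature for one protein."""
    if rtc.protein_id != pssm_f.protein_id:
        raise ValueError(
            f"protein id mismatch: {rtc.protein_id!r} vs {pssm_f.protein_id!r}"
        )
    if len(pssm_f) != 20:
        raise ValueError("PSSM feature must be 20-dimensional")
    return FeatureVector(
        rtc.protein_id,
        np.concatenate([rtc.values, pssm_f.values]),
        rtc.schema + pssm_f.schema,
    )


def rtcp_vector(
    seq: str, pssm: PSSMatrix, alphabet: ReducedAlphabet, protein_id: str = ""
) -> FeatureVector:
    """Convenience: full RTCP descriptor for one protein."""
    from .alphabets import reduce_sequence

    pid = protein_id or pssm.protein_id
    rtc = tripeptide_composition(reduce_sequence(seq, alphabet), alphabet.size, pid)
    pf = pssm_feature(PSSMatrix(pid, pssm.residues, pssm.scores))
    return assemble_rtcp(rtc, pf)


def amino_acid_composition(seq: str, protein_id: str = "") -> FeatureVector:
    """Relative frequency of each of the 20 standard residues (sums to 1)."""
    clean = sanitize_sequence(seq)
    if not clean:
        raise ValueError("empty sequence after sanitization")
    idx = {c: i for i, c in enumerate(AAC_COLUMNS)}
    counts = np.zeros(20)
    for c in clean:
        counts[idx[c]] += 1
    return FeatureVector(
        protein_id, counts / len(clean), tuple(f"aac_{c}" for c in AAC_COLUMNS)
    )


# ---------------------------------------------------------------------------
# dimensionality reduction


@dataclass
class Reducer:
    """A fitted PCA projection onto the top d_out principal axes.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making the projection deterministic across fits.
    """

    mean: np.ndarray
    components: np.ndarray  # d_out x p
    d_out: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) @ self.components.T

    @property
    def schema(self) -> tuple[str, ...]:
        return tuple(f"pc{i + 1}" for i in range(self.d_out))


def fit_reducer(X: np.ndarray, d_out: int = 80) -> Reducer:
    """Fit PCA on rows of X and keep the top ``d_out`` axes (default 80)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if d_out > min(n - 1, p):
        raise ValueError(
            f"d_out={d_out} exceeds min(n_samples-1={n - 1}, n_features={p})"
        )
    pca = PCA(n_components=d_out, svd_solver="full", random_state=0)
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return Reducer(mean=pca.mean_, components=comps, d_out=d_out)


def apply_reducer(reducer: Reducer, X: np.ndarray) -> np.ndarray:
    """Project rows of X with a fitted reducer; returns n x d_out."""
    return reducer.transform(X)


def feature_matrix(vectors: list[FeatureVector]) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Stack FeatureVectors sharing a schema into (matrix, ids, schema)."""
    if not vectors:
        raise ValueError("no feature vectors given")
    schema = vectors[0].schema
    for v in vectors:
        if v.schema != schema:
            raise ValueError("inconsistent feature schemas")
    X = np.vstack([v.values for v in vectors])
    return X, [v.protein_id for v in vectors], schema
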