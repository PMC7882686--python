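"""Synthetic two-class protein datasets with matching PSSM profiles.

The generator emulates the statistical structure the RTCP feature consumes,
not real transporter biology. Class signal is injected at the reduced-
alphabet level: each class draws reduced-symbol sequences from a first-order
Markov chain over alphabet classes, the two transition matrices being a
shared base matrix perturbed multiplicatively by +/- ``signal_strength`` on
a seeded subset of entries (rows re-normalized). Reduced symbols are then
back-translated to a uniformly random residue of their class, so the
reduced tripeptide composition is, by construction, the sufficient statistic
separating the classes. Synthetic PSSM scores are integer-rounded
Normal(0, 2) draws, with ``pssm_shift`` added to a seeded subset of columns
for class 1 to mimic class-linked conservation signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alphabets import ReducedAlphabet, canonical_alphabets
from .features import PSSMatrix, PSSM_COLUMNS


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults are the package's study conditions.

    ``signal_strength`` in [0, 1]: 0 makes the two classes statistically
    identical. ``pssm_shift`` is an additive mean shift applied to a random
    fifth of the PSSM columns for class 1.
    """

    n_per_class: int = 200
    length_range: tuple[int, int] = (50, 250)
    alphabet: ReducedAlphabet = field(
        default_factory=lambda: canonical_alphabets()["ST_SS"]
    )
    signal_strength: float = 0.5
    pssm_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError("length_range must satisfy 3 <= min <= max")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    ids: list[str]
    sequences: list[str]
    pssms: list[PSSMatrix]
    labels: np.ndarray
    spec: SyntheticSpec


def _transition_matrices(spec: SyntheticSpec, rng: np.random.Generator):
    k = spec.alphabet.size
    base = rng.dirichlet(np.full(k, 5.0), size=k)
    mask = rng.random((k, k)) < 0.3
    sign = np.where(rng.random((k, k)) < 0.5, -1.0, 1.0)
    shifted = base * (1.0 + spec.signal_strength * sign * mask)
    shifted = np.clip(shifted, 1e-9, None)
    shifted /= shifted.sum(axis=1, keepdims=True)
    return base, shifted


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a labeled synthetic dataset; byte-deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    t0, t1 = _transition_matrices(spec, rng)
    k = spec.alphabet.size
    shift_cols = rng.choice(20, size=max(1, 20 // 5), replace=False)
    lo, hi = spec.length_range

    ids, sequences, pssms, labels = [], [], [], []
    for label, trans in ((0, t0), (1, t1)):
        for i in range(spec.n_per_class):
            pid = f"syn{label}_{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            # reduced-symbol Markov walk
            symbols = np.empty(length, dtype=int)
            symbols[0] = rng.integers(k)
            for t in range(1, length):
                symbols[t] = rng.choice(k, p=trans[symbols[t - 1]])
            # back-translate: uniform residue within each reduced class
            seq = "".join(
                spec.alphabet.classes[s][rng.integers(len(spec.alphabet.classes[s]))]
                for s in symbols
            )
            scores = np.round(rng.normal(0.0, 2.0, size=(length, 20)))
            if label == 1:
                scores[:, shift_cols] += round(spec.pssm_shift)
            ids.append(pid)
            sequences.append(seq)
            pssms.append(PSSMatrix(pid, seq, scores))
            labels.append(label)
    return SyntheticDataset(ids, sequences, pssms, np.array(labels), spec)


# ---------------------------------------------------------------------------
# fixture files


_PSSM_HEADER = (
    "\n"
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts\n"
)


def format_pssm_ascii(m: PSSMatrix) -> str:
    """Render a PSSM in the PSI-BLAST ``-out_ascii_pssm`` text layout.

    Scores are written as integers (the native precision of the format);
    the weighted-percentage block is filled with zeros.
    """
    letters = "  ".join(PSSM_COLUMNS)
    lines = [_PSSM_HEADER.rstrip("\n"), f"            {letters}   {letters}"]
    for i, (res, row) in enumerate(zip(m.residues, m.scores), start=1):
        scores = " ".join(f"{int(round(v)):3d}" for v in row)
        pcts = " ".join("  0" for _ in range(20))
        lines.append(f"{i:5d} {res}  {scores}  {pcts}  0.00 0.00")
    lines.append("")
    lines.append("                      K         Lambda")
    lines.append("Standard Ungapped    0.1337     0.3177")
    return "\n".join(lines) + "\n"


def write_fixtures(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write FASTA, per-protein ASCII PSSMs, labels TSV, and a manifest.

    Files round-trip losslessly through the package's readers. Returns the
    manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    fasta = out / "sequences.fasta"
    with fasta.open("w") as fh:
        for pid, seq in zip(dataset.ids, dataset.sequences):
            fh.write(f">{pid}\n{seq}\n")
    for m in dataset.pssms:
        (out / "pssm" / f"{m.protein_id}.pssm").write_text(format_pssm_ascii(m))
    labels_path = out / "labels.tsv"
    with labels_path.open("w") as fh:
        for pid, lab in zip(dataset.ids, dataset.labels):
            fh.write(f"{pid}\t{int(lab)}\n")

    spec_dict = asdict(dataset.spec)
    spec_dict["alphabet"] = {
        "name": dataset.spec.alphabet.name,
        "classes": list(dataset.spec.alphabet.classes),
    }
    spec_json = json.dumps(spec_dict, sort_keys=True)
    manifest = {
        "spec": spec_dict,
        "seed": dataset.spec.seed,
        "spec_sha256": hashlib.sha256(spec_json.encode()).hexdigest(),
        "n_records": len(dataset.ids),
        "files": {
            "fasta": fasta.name,
            "labels": labels_path.name,
            "pssm_dir": "pssm",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
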