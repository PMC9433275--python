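"""Sliding-window dataset construction for per-residue PPII classification.

Every residue of a labeled sequence yields one fixed-length window sample
centered on it (terminal positions are padded with 'X'), so a sequence of
length L yields exactly L samples.  Class imbalance is handled by random
undersampling of the majority (negative) class; splits are stratified at
4:1 (train:val) or 3:1:1 (train:val:test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
ALPHABET = AMINO_ACIDS + PAD

SPLIT_SCHEMES = {
    "balanced_4to1": (("train", 4), ("val", 1)),
    "unbalanced_3to1to1": (("train", 3), ("val", 1), ("test", 1)),
}


@dataclass
class LabeledSequence:
    """A protein sequence with per-residue binary PPII labels ('0'/'1')."""

    id: str
    seq: str
    labels: str

    def __post_init__(self):
        if not self.seq:
            raise InputError(f"{self.id}: empty sequence")
        if len(self.seq) != len(self.labels):
            raise InputError(
                f"{self.id}: sequence length {len(self.seq)} != "
                f"label length {len(self.labels)}")
        bad = set(self.seq) - set(ALPHABET)
        if bad:
            raise InputError(f"{self.id}: unknown residue codes {sorted(bad)}")
        if set(self.labels) - {"0", "1"}:
            raise InputError(f"{self.id}: labels must be over {{0,1}}")


@dataclass
class WindowSample:
    """A window of width 2m+1 with the center residue's label."""

    source_id: str
    center: int
    window: str
    label: int


@dataclass
class DatasetSplit:
    train: list[WindowSample]
    val: list[WindowSample]
    test: list[WindowSample] = field(default_factory=list)
    seed: int = 0
    scheme: str = "balanced_4to1"

    def parts(self) -> dict[str, list[WindowSample]]:
        d = {"train": self.train, "val": self.val}
        if self.scheme == "unbalanced_3to1to1":
            d["test"] = self.test
        return d


def make_windows(s: LabeledSequence, w: int) -> list[WindowSample]:
    """One window sample per residue; termini padded with 'X'.

    The window count equals the sequence length for every w, which keeps the
    per-residue sample bookkeeping exact.
    """
    if w < 1 or w % 2 == 0:
        raise ConfigError(f"window size must be odd and >= 1, got {w}")
    m = w // 2
    padded = PAD * m + s.seq + PAD * m
    return [
        WindowSample(source_id=s.id, center=c,
                     window=padded[c:c + w], label=int(s.labels[c]))
        for c in range(len(s.seq))
    ]


def make_all_windows(seqs: Iterable[LabeledSequence],
                     w: int) -> list[WindowSample]:
    out: list[WindowSample] = []
    for s in seqs:
        out.extend(make_windows(s, w))
    return out


def undersample_balance(samples: Sequence[WindowSample],
                        seed: int | np.random.Generator) -> list[WindowSample]:
    """Keep all positives; draw an equal number of negatives uniformly
    without replacement.  Deterministic for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos:
        raise InputError("undersample_balance: no positive samples")
    if len(neg) < len(pos):
        raise InputError(
            f"undersample_balance: negatives ({len(neg)}) fewer than "
            f"positives ({len(pos)}); expected negative-majority data")
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    return pos + [neg[i] for i in sorted(keep)]


def _apportion(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of `total` into len(weights) parts."""
    wsum = sum(weights)
    ideal = [total * w / wsum for w in weights]
    sizes = [int(x) for x in ideal]
    rema = sorted(range(len(weights)), key=lambda i: ideal[i] - sizes[i],
                  reverse=True)
    for i in rema[: total - sum(sizes)]:
        sizes[i] += 1
    return sizes


def split(samples: Sequence[WindowSample], scheme: str,
          seed: int) -> DatasetSplit:
    """Stratified split at the scheme's ratio, deterministic per seed.

    Part sizes follow largest-remainder apportionment on the total, and the
    per-class allocation is pinned to those totals, so every part lands
    within one sample of its ideal share overall and per class.
    """
    if scheme not in SPLIT_SCHEMES:
        raise ConfigError(f"unknown split scheme: {scheme!r}; "
                          f"expected one of {sorted(SPLIT_SCHEMES)}")
    part_names = [n for n, _ in SPLIT_SCHEMES[scheme]]
    weights = [w for _, w in SPLIT_SCHEMES[scheme]]
    n = len(samples)
    totals = _apportion(n, weights)
    for name, size in zip(part_names, totals):
        if size == 0:
            raise InputError(f"split: too few samples, part {name!r} empty")

    rng = np.random.default_rng(seed)
    pos_idx = [i for i, s in enumerate(samples) if s.label == 1]
    neg_idx = [i for i, s in enumerate(samples) if s.label == 0]
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    pos_sizes = _apportion(len(pos_idx), weights)
    # Pin the negative allocation so part totals are met exactly.
    neg_sizes = [t - p for t, p in zip(totals, pos_sizes)]
    if any(s < 0 for s in neg_sizes):
        neg_sizes = _apportion(len(neg_idx), weights)

    parts: dict[str, list[WindowSample]] = {}
    p0 = n0 = 0
    for name, ps, ns in zip(part_names, pos_sizes, neg_sizes):
        chosen = pos_idx[p0:p0 + ps] + neg_idx[n0:n0 + ns]
        p0 += ps
        n0 += ns
        order = rng.permutation(len(chosen))
        parts[name] = [samples[chosen[i]] for i in order]
    return DatasetSplit(train=parts["train"], val=parts["val"],
                        test=parts.get("test", []), seed=seed, scheme=scheme)


def composition(samples: Sequence[WindowSample]) -> pd.DataFrame:
    """Relative frequency of each amino acid at the center position, per class.

    Columns ``ppii`` and ``non_ppii`` each sum to 1; pad characters at the
    center (possible only for empty-context corner cases) are excluded.
    """
    if not samples:
        raise InputError("composition: empty input")
    counts = {0: {a: 0 for a in AMINO_ACIDS}, 1: {a: 0 for a in AMINO_ACIDS}}
    for s in samples:
        center_aa = s.window[len(s.window) // 2]
        if center_aa in counts[s.label]:
            counts[s.label][center_aa] += 1
    df = pd.DataFrame({
        "ppii": pd.Series(counts[1], dtype=float),
        "non_ppii": pd.Series(counts[0], dtype=float),
    })
    for col in df.columns:
        total = df[col].sum()
        if total > 0:
            df[col] /= total
    df.index.name = "aa"
    return df


def link_structure_labels(annotations: pd.DataFrame,
                          sequences: Sequence[tuple[str, str]],
                          mode: str = "strict") -> list[LabeledSequence]:
    """Join per-residue structure annotations with sequences by chain id."""
    col = {"strict": "label_strict", "less_strict": "label_less_strict"}.get(mode)
    if col is None:
        raise ConfigError(f"unknown mode: {mode!r}")
    by_chain = {cid: grp for cid, grp in annotations.groupby("chain_id", sort=False)}
    out = []
    problems = []
    for sid, seq in sequences:
        grp = by_chain.get(sid)
        if grp is None:
            problems.append(f"{sid}: no annotation rows")
            continue
        if len(grp) != len(seq):
            problems.append(
                f"{sid}: {len(grp)} annotation rows vs sequence length {len(seq)}")
            continue
        labels = "".join(str(int(v)) for v in grp[col])
        out.append(LabeledSequence(id=sid, seq=seq, labels=labels))
    if problems:
        raise InputError("annotation/sequence mismatch: " + "; ".join(problems))
    return out


# ---------------------------------------------------------------------------
# serialization

def read_fasta(path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records],
        str(path), "fasta")


def write_labels_tsv(seqs: Sequence[LabeledSequence], path) -> None:
    """Per-residue label table: one row per residue."""
    rows = [
        {"id": s.id, "position": i, "aa": s.seq[i], "label": int(s.labels[i])}
        for s in seqs for i in range(len(s.seq))
    ]
    pd.DataFrame(rows, columns=["id", "position", "aa", "label"]).to_csv(
        path, sep="\t", index=False)


def read_labels_tsv(path) -> list[LabeledSequence]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "aa": str})
    out = []
    for sid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        if not (grp["position"].to_numpy() == np.arange(len(grp))).all():
            raise InputError(f"{sid}: label table positions are not 0..L-1")
        out.append(LabeledSequence(
            id=str(sid), seq="".join(grp["aa"]),
            labels="".join(str(int(v)) for v in grp["label"])))
    if not out:
        raise InputError(f"no label rows in {path}")
    return out


def write_samples_tsv(samples: Sequence[WindowSample], path) -> None:
    pd.DataFrame(
        [{"source_id": s.source_id, "center": s.center,
          "window": s.window, "label": s.label} for s in samples],
        columns=["source_id", "center", "window", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> list[WindowSample]:
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "window": str})
    return [WindowSample(source_id=r.source_id, center=int(r.center),
                         window=r.window, label=int(r.label))
            for r in df.itertuples()]


def write_split(ds: DatasetSplit, out_dir) -> None:
    """Write one samples TSV per part plus a JSON manifest that makes the
    split reconstructible (ids + seed + scheme)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": ds.seed, "scheme": ds.scheme, "parts": {}}
    for name, part in ds.parts().items():
        write_samples_tsv(part, out_dir / f"{name}.tsv")
        manifest["parts"][name] = {
            "n": len(part),
            "n_pos": sum(s.label for s in part),
            "ids": [f"{s.source_id}:{s.center}" for s in part],
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_split(in_dir) -> DatasetSplit:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    parts = {name: read_samples_tsv(in_dir / f"{name}.tsv")
             for name in manifest["parts"]}
    return DatasetSplit(train=parts["train"], val=parts["val"],
                        test=parts.get("test", []),
                        seed=manifest["seed"], scheme=manifest["scheme"])
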