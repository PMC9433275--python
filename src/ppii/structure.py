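"""PPII helix assignment from backbone dihedral angles.

A residue is a PPII candidate when its psi lies in (-180, -160) or (90, 180)
and — under the strict definition — its phi lies in (-105, -45) and the
CA-trace pseudo-torsion (the virtual dihedral over four consecutive alpha
carbons CA(i-1)..CA(i+2), about -109 deg for ideal trans PPII and positive
for cis or alpha-helical geometry) lies in (-145, -70).  The less strict
definition drops the phi requirement.  Maximal runs of candidates of length
>= 3 whose mean consecutive (phi, psi) displacement (the regularization
score) stays below a uniformity threshold are assigned as PPII segments.

Coordinate files (PDB/mmCIF) are read with gemmi; all dihedrals are computed
here from the backbone atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
import pandas as pd

from .errors import GeometryError, InputError, ParseError
from .geometry import dihedral, wrap_angle

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Consecutive residues farther apart than this (C to next N, angstroms) are
# treated as a chain break: no dihedral is computed across the gap.
PEPTIDE_BOND_CUTOFF = 2.0


@dataclass
class ResidueGeometry:
    """One residue's identity and backbone dihedrals (degrees, (-180, 180])."""

    chain_id: str
    author_seq_id: int
    index: int
    aa: str
    phi_deg: Optional[float] = None
    psi_deg: Optional[float] = None
    trans_angle_deg: Optional[float] = None


@dataclass
class FilterConfig:
    """Thresholds of the PPII assignment filters.

    All intervals are open (strict inequalities).  In ``less_strict`` mode the
    phi band is not applied; the trans band applies in strict mode only and
    only where the virtual torsion is computable.  ``score_divisor`` selects
    the regularization-score normalization: ``"pairs"`` (mean over the n-1
    consecutive pairs) or ``"length"`` (divide by n).
    """

    mode: str = "strict"
    psi_band_1: tuple[float, float] = (-180.0, -160.0)
    psi_band_2: tuple[float, float] = (90.0, 180.0)
    phi_band: tuple[float, float] = (-105.0, -45.0)
    trans_band: tuple[float, float] = (-145.0, -70.0)
    regularization_threshold_tau: float = 30.0
    min_segment_length: int = 3
    score_divisor: str = "pairs"

    def __post_init__(self):
        if self.mode not in ("strict", "less_strict"):
            raise InputError(f"unknown filter mode: {self.mode!r}")
        for name in ("psi_band_1", "psi_band_2", "phi_band", "trans_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InputError(f"{name}: lower bound must be < upper bound")
        if self.min_segment_length < 1:
            raise InputError("min_segment_length must be >= 1")
        if self.regularization_threshold_tau <= 0:
            raise InputError("regularization_threshold_tau must be > 0")
        if self.score_divisor not in ("pairs", "length"):
            raise InputError(f"unknown score_divisor: {self.score_divisor!r}")


@dataclass
class PPIISegment:
    """A maximal accepted run of PPII residues, inclusive 0-based indices."""

    chain_id: str
    start_index: int
    end_index: int
    mode: str
    regularization_score: float


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueGeometry] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _best_atom(residue: gemmi.Residue, name: str) -> Optional[np.ndarray]:
    """Position of the named atom, resolving altlocs to highest occupancy."""
    best = None
    for atom in residue:
        if atom.name == name:
            if best is None or atom.occ > best.occ:
                best = atom
    if best is None:
        return None
    return np.array([best.pos.x, best.pos.y, best.pos.z])


def parse_structure(path, fmt: str = "auto") -> list[Chain]:
    """Read a PDB or mmCIF file into chains of :class:`ResidueGeometry`.

    Polymer residues are those with N, CA and C backbone atoms from ATOM
    records; nonstandard residues map to 'X'.  Dihedrals are computed wherever
    all four defining atoms exist and consecutive residues are peptide-bonded
    (C..N distance under 2 angstroms).  Chains with fewer than two usable
    residues are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise InputError(f"unknown structure format: {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc

    chains: list[Chain] = []
    if len(st) == 0:
        return chains
    model = st[0]
    for gchain in model:
        entries = []  # (gemmi residue, coords dict)
        for res in gchain:
            if res.het_flag == "H":
                continue
            coords = {n: _best_atom(res, n) for n in ("N", "CA", "C")}
            if any(v is None for v in coords.values()):
                continue
            entries.append((res, coords))
        if len(entries) < 2:
            if entries or len(gchain) > 0:
                logger.warning(
                    "chain %s skipped: fewer than 2 polymer residues with "
                    "complete backbone", gchain.name)
            continue

        chain = Chain(chain_id=gchain.name)
        n = len(entries)
        bonded = []  # bonded[i] is True when residue i+1 follows residue i
        for i in range(n - 1):
            d = np.linalg.norm(entries[i][1]["C"] - entries[i + 1][1]["N"])
            bonded.append(d < PEPTIDE_BOND_CUTOFF)
        for i, (res, xyz) in enumerate(entries):
            aa = THREE_TO_ONE.get(res.name.upper().strip(), "X")
            rg = ResidueGeometry(
                chain_id=gchain.name,
                author_seq_id=res.seqid.num,
                index=i,
                aa=aa,
            )
            prev_ok = i > 0 and bonded[i - 1]
            next_ok = i < n - 1 and bonded[i]
            next2_ok = next_ok and i < n - 2 and bonded[i + 1]
            try:
                if prev_ok:
                    rg.phi_deg = dihedral(entries[i - 1][1]["C"], xyz["N"],
                                          xyz["CA"], xyz["C"])
                if next_ok:
                    rg.psi_deg = dihedral(xyz["N"], xyz["CA"], xyz["C"],
                                          entries[i + 1][1]["N"])
                if prev_ok and next2_ok:
                    # CA-trace pseudo-torsion (alpha): CA(i-1)..CA(i+2)
                    rg.trans_angle_deg = dihedral(
                        entries[i - 1][1]["CA"], xyz["CA"],
                        entries[i + 1][1]["CA"], entries[i + 2][1]["CA"])
            except GeometryError:
                logger.warning("degenerate backbone geometry at %s %s%d",
                               gchain.name, res.name, res.seqid.num)
            chain.residues.append(rg)
        chains.append(chain)
    return chains


def _in_open(value: float, band: tuple[float, float]) -> bool:
    return band[0] < value < band[1]


def passes_dihedral_filter(r: ResidueGeometry, cfg: FilterConfig) -> bool:
    """Per-residue dihedral (and, strict mode, trans) filter.

    False whenever phi or psi is undefined: an open interval cannot be
    satisfied by an absent angle.
    """
    if r.phi_deg is None or r.psi_deg is None:
        return False
    if not (_in_open(r.psi_deg, cfg.psi_band_1)
            or _in_open(r.psi_deg, cfg.psi_band_2)):
        return False
    if cfg.mode == "strict":
        if not _in_open(r.phi_deg, cfg.phi_band):
            return False
        if r.trans_angle_deg is not None and not _in_open(
                r.trans_angle_deg, cfg.trans_band):
            return False
    return True


def regularization_score(segment_phis, segment_psis,
                         divisor: str = "pairs") -> float:
    """Mean consecutive-residue displacement in (phi, psi) space, degrees.

    d(k, k+1) = sqrt(wrap(psi_k - psi_{k+1})^2 + wrap(phi_k - phi_{k+1})^2),
    averaged over the n-1 consecutive pairs (``divisor="pairs"``) or divided
    by n (``divisor="length"``).  Angular differences are wrapped into
    (-180, 180] so a pair like (179, -179) contributes 2, not 358.
    """
    phis = np.asarray(segment_phis, dtype=float)
    psis = np.asarray(segment_psis, dtype=float)
    if phis.shape != psis.shape or phis.ndim != 1:
        raise InputError("phi and psi lists must be equal-length 1-D")
    n = len(phis)
    if n < 2:
        raise InputError("regularization score needs a segment of length >= 2")
    dphi = wrap_angle(phis[:-1] - phis[1:])
    dpsi = wrap_angle(psis[:-1] - psis[1:])
    total = float(np.sum(np.hypot(dpsi, dphi)))
    return total / (n - 1 if divisor == "pairs" else n)


def assign_ppii(chain: Iterable[ResidueGeometry] | Chain,
                cfg: FilterConfig) -> tuple[list[str], list[PPIISegment]]:
    """Label each residue PPII/non-PPII and return accepted segments.

    Maximal runs of residues passing the per-residue filter become candidate
    segments; a candidate is accepted when it is at least
    ``cfg.min_segment_length`` long and its regularization score does not
    exceed ``cfg.regularization_threshold_tau``.
    """
    residues = chain.residues if isinstance(chain, Chain) else list(chain)
    if not residues:
        raise InputError("assign_ppii: empty chain")
    chain_id = residues[0].chain_id
    passing = [passes_dihedral_filter(r, cfg) for r in residues]
    labels = ["non-PPII"] * len(residues)
    segments: list[PPIISegment] = []

    i = 0
    n = len(residues)
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        length = j - i + 1
        if length >= cfg.min_segment_length:
            run = residues[i:j + 1]
            score = regularization_score(
                [r.phi_deg for r in run], [r.psi_deg for r in run],
                divisor=cfg.score_divisor)
            if score <= cfg.regularization_threshold_tau:
                segments.append(PPIISegment(
                    chain_id=chain_id, start_index=i, end_index=j,
                    mode=cfg.mode, regularization_score=score))
                for k in range(i, j + 1):
                    labels[k] = "PPII"
        i = j + 1
    return labels, segments


def annotate(chains: list[Chain],
             cfg_strict: Optional[FilterConfig] = None,
             cfg_less: Optional[FilterConfig] = None,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue annotation and segment tables under both definitions."""
    cfg_strict = cfg_strict or FilterConfig(mode="strict")
    cfg_less = cfg_less or FilterConfig(
        mode="less_strict",
        regularization_threshold_tau=cfg_strict.regularization_threshold_tau,
        min_segment_length=cfg_strict.min_segment_length,
        score_divisor=cfg_strict.score_divisor)
    rows = []
    seg_rows = []
    for chain in chains:
        lab_s, seg_s = assign_ppii(chain, cfg_strict)
        lab_l, seg_l = assign_ppii(chain, cfg_less)
        for r, ls, ll in zip(chain.residues, lab_s, lab_l):
            rows.append({
                "chain_id": r.chain_id,
                "author_seq_id": r.author_seq_id,
                "aa": r.aa,
                "phi_deg": r.phi_deg,
                "psi_deg": r.psi_deg,
                "trans_angle_deg": r.trans_angle_deg,
                "label_strict": 1 if ls == "PPII" else 0,
                "label_less_strict": 1 if ll == "PPII" else 0,
            })
        for seg in seg_s + seg_l:
            seg_rows.append({
                "chain_id": seg.chain_id,
                "start": seg.start_index,
                "end": seg.end_index,
                "mode": seg.mode,
                "regularization_score": seg.regularization_score,
            })
    ann = pd.DataFrame(rows, columns=[
        "chain_id", "author_seq_id", "aa", "phi_deg", "psi_deg",
        "trans_angle_deg", "label_strict", "label_less_strict"])
    segs = pd.DataFrame(seg_rows, columns=[
        "chain_id", "start", "end", "mode", "regularization_score"])
    return ann, segs


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_segments_tsv(segs: pd.DataFrame, path,
                       cfg: Optional[FilterConfig] = None) -> None:
    cfg = cfg or FilterConfig()
    with open(path, "w") as fh:
        fh.write(f"# tau={cfg.regularization_threshold_tau} "
                 f"min_segment_length={cfg.min_segment_length} "
                 f"score_divisor={cfg.score_divisor}\n")
        segs.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
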