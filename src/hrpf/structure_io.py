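"""Structure, protection-factor and score-table I/O.

Structures are read from PDB files (single- or multi-MODEL, or a directory
of files) into lightweight :class:`ProteinModel` objects holding per-residue
CA/CB (and backbone N, C) coordinates.  Protection factors (PF) arrive as
tab-separated tables, either directly as a PF column or as an experimental
labeling rate constant ``k`` plus intrinsic reactivity ``R``, from which
``lnPF = ln(R/k)``.  Score tables round-trip at full float precision and a
Rosetta-style whitespace scorefile is accepted read-only.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("hrpf")

AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO1_TO_3 = {v: k for k, v in AMINO3_TO_1.items()}

#: labeled residue types used for scoring by default (high-to-intermediate
#: intrinsic reactivity; C and M are excluded as overly reactive)
DEFAULT_RESIDUE_FILTER = frozenset("WYFHL")


@dataclass
class Residue:
    """One amino-acid residue with the coordinates the exposure metric needs.

    ``cb`` is absent only for glycine; ``n``/``c`` backbone coordinates are
    kept when available so a pseudo-CB can be constructed.
    """

    chain_id: str
    seq_num: int
    res_type: str
    ca: np.ndarray
    cb: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    icode: str = ""

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_num)


@dataclass
class ProteinModel:
    """A single structural model: ordered residues plus an identity tag."""

    model_id: str
    residues: list[Residue]
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: (r.chain_id, r.seq_num, r.icode))
        keys = [(r.chain_id, r.seq_num, r.icode) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise FormatError(f"duplicate residue keys in model {self.model_id!r}")

    def residue(self, chain_id: str, seq_num: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_num == seq_num:
                return r
        raise KeyError((chain_id, seq_num))

    def residue_map(self) -> dict[tuple[str, int], Residue]:
        return {r.key: r for r in self.residues}


@dataclass
class PFRecord:
    """Protection factor for one labeled residue.

    Exactly one of ``pf`` or (``rate_k``, ``reactivity_R``) is supplied;
    ``lnpf`` is ln(pf) or ln(R/k).  ``active`` marks residues whose type is
    inside the residue filter; inactive records are retained but never scored.
    """

    chain_id: str
    seq_num: int
    res_type: str
    lnpf: float
    pf: Optional[float] = None
    rate_k: Optional[float] = None
    reactivity_R: Optional[float] = None
    active: bool = True


@dataclass
class PFTable:
    """Residue-resolved protection factors with an active-residue filter."""

    records: list[PFRecord]
    residue_filter: frozenset[str] = DEFAULT_RESIDUE_FILTER

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.seq_num) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chain, resnum) in PF table")

    @property
    def active_records(self) -> list[PFRecord]:
        return [r for r in self.records if r.active]


@dataclass
class SSESpec:
    """Residues belonging to helix/sheet secondary-structure elements."""

    residues: set[tuple[str, int]]
    source: str = "pdb_records"


# ---------------------------------------------------------------------------
# structure reading

def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def _convert_model(model: gemmi.Model, model_id: str, source: str) -> ProteinModel:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.het_flag != "A":
                continue
            one = AMINO3_TO_1.get(res.name.upper())
            if one is None:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            coords = {}
            for name in ("CA", "CB", "N", "C"):
                if name in by_name:
                    a = _pick_altloc(by_name[name])
                    coords[name] = np.array([a.pos.x, a.pos.y, a.pos.z])
            if "CA" not in coords:
                continue
            residues.append(Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                res_type=one,
                ca=coords["CA"],
                cb=coords.get("CB"),
                n=coords.get("N"),
                c=coords.get("C"),
                icode=res.seqid.icode.strip(),
            ))
    if not residues:
        raise FormatError(f"model {model_id!r} in {source} contains no CA atoms")
    return ProteinModel(model_id=model_id, residues=residues, source=source)


def read_models(path: str | Path, max_models: Optional[int] = None) -> list[ProteinModel]:
    """Read a PDB file (single- or multi-MODEL) or a directory of PDB files.

    Returns one :class:`ProteinModel` per MODEL record / per file (files
    ordered by name).  HETATM records are ignored and alternate locations
    resolved to the highest occupancy.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".pdb", ".ent"))
        if not files:
            raise FormatError(f"no PDB files found in directory {path}")
        models: list[ProteinModel] = []
        for f in files:
            models.extend(read_models(f))
            if max_models is not None and len(models) >= max_models:
                return models[:max_models]
        return models
    if not path.is_file():
        raise FormatError(f"cannot read structure file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to parse PDB file {path}: {exc}") from exc
    models = []
    multi = len(st) > 1
    for i, gm in enumerate(st):
        mid = f"{path.stem}_m{i + 1}" if multi else path.stem
        models.append(_convert_model(gm, mid, f"{path}#{i}"))
        if max_models is not None and len(models) >= max_models:
            break
    return models


def write_models(models: Iterable[ProteinModel], path: str | Path) -> None:
    """Write models as a multi-MODEL PDB file (CA/CB/N/C atoms only)."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    for i, model in enumerate(models):
        gm = gemmi.Model(i + 1)
        chains: dict[str, gemmi.Chain] = {}
        for r in model.residues:
            ch = chains.get(r.chain_id)
            if ch is None:
                ch = gemmi.Chain(r.chain_id)
                chains[r.chain_id] = ch
            gr = gemmi.Residue()
            gr.name = AMINO1_TO_3[r.res_type]
            gr.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
            gr.het_flag = "A"
            for name, xyz, elem in (("N", r.n, "N"), ("CA", r.ca, "C"),
                                    ("C", r.c, "C"), ("CB", r.cb, "C")):
                if xyz is None:
                    continue
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(elem)
                a.pos = gemmi.Position(*map(float, xyz))
                a.occ = 1.0
                gr.add_atom(a)
            ch.add_residue(gr)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# protection factor tables

def read_pf_table(path: str | Path,
                  residue_filter: Iterable[str] = DEFAULT_RESIDUE_FILTER) -> PFTable:
    """Read a tab-separated PF table.

    Expects a header with columns ``chain  resnum  restype`` plus either
    ``pf`` or both ``k`` and ``R``.  Residue types outside *residue_filter*
    are retained but flagged inactive.
    """
    residue_filter = frozenset(residue_filter)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise FormatError(f"cannot read PF table {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    required = {"chain", "resnum", "restype"}
    if not required.issubset(df.columns):
        raise FormatError(f"PF table {path} missing columns {required - set(df.columns)}")
    has_pf = "pf" in df.columns
    has_kr = "k" in df.columns and "R" in df.columns
    if not has_pf and not has_kr:
        raise FormatError(f"PF table {path} needs a 'pf' column or 'k' and 'R' columns")
    records = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        restype = str(row["restype"]).strip().upper()
        if len(restype) == 3:
            restype = AMINO3_TO_1.get(restype, restype)
        if restype not in AMINO1_TO_3:
            raise ValidationError(f"{path} row {rownum}: unknown residue type {restype!r}")
        pf = row.get("pf") if has_pf else None
        k = row.get("k") if has_kr else None
        R = row.get("R") if has_kr else None
        pf_given = pf is not None and not pd.isna(pf)
        kr_given = has_kr and not pd.isna(k) and not pd.isna(R)
        if pf_given and kr_given:
            raise ValidationError(f"{path} row {rownum}: both pf and k/R supplied")
        if pf_given:
            pf = float(pf)
            if pf <= 0:
                raise ValidationError(f"{path} row {rownum}: pf must be > 0, got {pf}")
            lnpf = math.log(pf)
            rec = PFRecord(str(row["chain"]).strip(), int(row["resnum"]), restype,
                           lnpf=lnpf, pf=pf)
        elif kr_given:
            k, R = float(k), float(R)
            if k <= 0 or R <= 0:
                raise ValidationError(f"{path} row {rownum}: k and R must be > 0")
            rec = PFRecord(str(row["chain"]).strip(), int(row["resnum"]), restype,
                           lnpf=math.log(R / k), pf=R / k, rate_k=k, reactivity_R=R)
        else:
            raise ValidationError(f"{path} row {rownum}: neither pf nor k/R supplied")
        rec.active = rec.res_type in residue_filter
        records.append(rec)
    return PFTable(records=records, residue_filter=residue_filter)


def write_pf_table(table: PFTable, path: str | Path) -> None:
    """Write a PF table as TSV (``chain resnum restype pf`` columns)."""
    rows = [{"chain": r.chain_id, "resnum": r.seq_num, "restype": r.res_type,
             "pf": repr(float(r.pf)) if r.pf is not None else repr(math.exp(r.lnpf))}
            for r in table.records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# secondary structure elements

_RANGE_RE = re.compile(r"^([A-Za-z0-9]):(\d+)-(\d+)$")


def parse_sse_ranges(ranges: Iterable[str]) -> SSESpec:
    """Build an :class:`SSESpec` from user strings like ``"A:5-10"``."""
    residues: set[tuple[str, int]] = set()
    for spec in ranges:
        m = _RANGE_RE.match(spec.strip())
        if not m:
            raise ValidationError(f"bad SSE range {spec!r}; expected CHAIN:START-END")
        chain, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
        if hi < lo:
            raise ValidationError(f"bad SSE range {spec!r}: end before start")
        residues.update((chain, i) for i in range(lo, hi + 1))
    return SSESpec(residues=residues, source="user")


def extract_sse_residues(path: str | Path,
                         user_ranges: Optional[Iterable[str]] = None) -> SSESpec:
    """Union of all HELIX/SHEET residue ranges in a PDB file (author numbering,
    inclusive endpoints).  Falls back to *user_ranges* when the file carries
    no secondary-structure records."""
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"cannot read structure file: {path}")
    st = gemmi.read_pdb(str(path))
    residues: set[tuple[str, int]] = set()
    for helix in st.helices:
        chain = helix.start.chain_name
        lo, hi = helix.start.res_id.seqid.num, helix.end.res_id.seqid.num
        residues.update((chain, i) for i in range(lo, hi + 1))
    for sheet in st.sheets:
        for strand in sheet.strands:
            chain = strand.start.chain_name
            lo, hi = strand.start.res_id.seqid.num, strand.end.res_id.seqid.num
            residues.update((chain, i) for i in range(lo, hi + 1))
    if residues:
        return SSESpec(residues=residues, source="pdb_records")
    if user_ranges:
        return parse_sse_ranges(user_ranges)
    raise ValidationError(
        f"{path} has no HELIX/SHEET records; supply SSE ranges explicitly "
        "(e.g. 'A:5-10')")


# ---------------------------------------------------------------------------
# score tables

SCORE_COLUMNS = ["model_id", "base_score", "hrf_dynamics", "total_score", "rmsd"]


def write_score_table(records: Sequence, path: str | Path) -> None:
    """Write ScoreRecords as TSV at full float precision (repr round-trip)."""
    lines = ["\t".join(SCORE_COLUMNS)]
    for r in records:
        rmsd = "" if r.rmsd is None else repr(float(r.rmsd))
        lines.append("\t".join([r.model_id, repr(float(r.base_score)),
                                repr(float(r.hrf_score)),
                                repr(float(r.total_score)), rmsd]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_score_table(path: str | Path) -> list:
    """Read a score table written by :func:`write_score_table`, or a
    Rosetta-style whitespace scorefile with ``score``/``rms`` columns."""
    from .hrpf_scoring import ScoreRecord  # local import: avoid cycle

    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if "\t" in first and "model_id" in first:
        df = pd.read_csv(path, sep="\t")
        records = []
        for _, row in df.iterrows():
            rmsd = row.get("rmsd")
            records.append(ScoreRecord(
                model_id=str(row["model_id"]),
                base_score=float(row["base_score"]),
                hrf_score=float(row["hrf_dynamics"]),
                total_score=float(row["total_score"]),
                rmsd=None if pd.isna(rmsd) else float(rmsd)))
        return records
    return _read_rosetta_scorefile(path)


def _read_rosetta_scorefile(path: Path) -> list:
    from .hrpf_scoring import ScoreRecord

    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    # Rosetta scorefiles prefix rows with "SCORE:"; a SEQUENCE line may lead
    lines = [ln[6:] if ln.startswith("SCORE:") else ln
             for ln in lines if not ln.startswith("SEQUENCE")]
    header = lines[0].split()
    if "score" not in header:
        raise ValidationError(f"{path}: no 'score' column found for base scores")
    i_score = header.index("score")
    i_rms = header.index("rms") if "rms" in header else None
    i_desc = header.index("description") if "description" in header else len(header) - 1
    records = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != len(header):
            continue
        records.append(ScoreRecord(
            model_id=parts[i_desc],
            base_score=float(parts[i_score]),
            hrf_score=0.0,
            total_score=float(parts[i_score]),
            rmsd=float(parts[i_rms]) if i_rms is not None else None))
    return records


def read_base_scores(path: str | Path) -> dict[str, float]:
    """Read per-model base (Ref15) scores into a ``model_id -> score`` map.

    Accepts a two-column TSV (``model_id  base_score``), a full score table,
    or a Rosetta whitespace scorefile.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if "\t" in first:
        df = pd.read_csv(path, sep="\t")
        if "model_id" not in df.columns or "base_score" not in df.columns:
            raise ValidationError(f"{path}: need 'model_id' and 'base_score' columns")
        return {str(r["model_id"]): float(r["base_score"]) for _, r in df.iterrows()}
    return {r.model_id: r.base_score for r in _read_rosetta_scorefile(path)}
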