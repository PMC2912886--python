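"""Strict readers and writers for every external format the pipeline touches.

Sequences travel as FASTA, motifs as MEME minimal format, numeric tracks
(concentrations, expression, CC matrices) as TSV with an ``id`` first column,
and run configuration as YAML. All parsing fails loudly: duplicate ids,
ragged tables, non-numeric cells and alphabet violations raise ``ValueError``
naming the offending record or coordinate. Lines starting with ``#`` in TSV
files are treated as comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .site_scanner import PWM, TFBS, TFBSMap, UNIFORM_BACKGROUND

DNA_CHARS = frozenset("ACGT")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ALPHABETS = {"dna": DNA_CHARS, "protein": PROTEIN_CHARS}


@dataclass
class SequenceSet:
    """Ordered, uniquely-keyed set of DNA or protein sequences."""

    records: list[tuple[str, str]]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"alphabet must be 'dna' or 'protein', got {self.alphabet!r}")
        allowed = _ALPHABETS[self.alphabet]
        seen: set[str] = set()
        clean: list[tuple[str, str]] = []
        for rec_id, seq in self.records:
            if not rec_id:
                raise ValueError("empty sequence id")
            if rec_id in seen:
                raise ValueError(f"duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"sequence {rec_id!r} is empty")
            for pos, ch in enumerate(seq):
                if ch not in allowed:
                    raise ValueError(
                        f"sequence {rec_id!r}: illegal character {ch!r} at position {pos}"
                    )
            clean.append((rec_id, seq))
        self.records = clean

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> str:
        for rid, seq in self.records:
            if rid == rec_id:
                return seq
        raise KeyError(rec_id)

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        wanted = set(ids)
        return SequenceSet([r for r in self.records if r[0] in wanted], self.alphabet)


@dataclass
class ProfileSet:
    """Per-track value vectors over a strictly increasing positional axis."""

    axis: np.ndarray
    profiles: dict[str, np.ndarray]
    non_negative: bool = False

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or axis.size == 0:
            raise ValueError("axis must be a non-empty 1-D array")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis positions must be strictly increasing")
        profiles: dict[str, np.ndarray] = {}
        for track, values in self.profiles.items():
            v = np.asarray(values, dtype=float)
            if v.shape != axis.shape:
                raise ValueError(
                    f"track {track!r}: length {v.size} does not match axis length {axis.size}"
                )
            if self.non_negative and np.any(v < 0):
                raise ValueError(f"track {track!r}: negative value in non-negative profile")
            profiles[track] = v
        self.axis = axis
        self.profiles = profiles

    @property
    def tracks(self) -> list[str]:
        return list(self.profiles)

    def __getitem__(self, track: str) -> np.ndarray:
        return self.profiles[track]

    def __contains__(self, track: str) -> bool:
        return track in self.profiles

    def matrix(self, order: Sequence[str]) -> np.ndarray:
        """Stack the named tracks into a ``len(order) x len(axis)`` array."""
        return np.stack([self.profiles[t] for t in order])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "dna") -> SequenceSet:
    """Read a FASTA file into a validated :class:`SequenceSet`."""
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    try:
        return SequenceSet(records, alphabet=alphabet)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70,
                header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f";{header_comment}\n")
        for rec_id, seq in seqs.records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
#
# Hand-rolled on purpose: we need symmetrical strict read/write with row-sum
# diagnostics, and Biopython has no MEME-minimal writer.

_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)")
_LPM_RE = re.compile(r"^letter-probability matrix:(.*)$")


def read_pwm_meme(path: str | Path, background: np.ndarray | None = None) -> list[PWM]:
    """Parse a MEME minimal-format motif file into a list of :class:`PWM`.

    Probability rows must sum to 1 within 1e-3 and are renormalized exactly.
    The file's "Background letter frequencies" section is used unless an
    explicit ``background`` is given. Only the ACGT alphabet is accepted.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    file_bg: np.ndarray | None = None
    pwms: list[PWM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not _MOTIF_RE.match(lines[i]):
                tokens.extend(lines[i].split())
                i += 1
            freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            if set(freqs) != set("ACGT"):
                raise ValueError(f"{path}: background must cover exactly A, C, G, T")
            file_bg = np.array([freqs[b] for b in "ACGT"])
            continue
        m = _MOTIF_RE.match(line)
        if m:
            name = m.group(1)
            i += 1
            while i < n and not _LPM_RE.match(lines[i].strip()):
                if _MOTIF_RE.match(lines[i].strip()):
                    raise ValueError(f"{path}: motif {name!r} has no letter-probability matrix")
                i += 1
            if i == n:
                raise ValueError(f"{path}: motif {name!r} has no letter-probability matrix")
            header = _LPM_RE.match(lines[i].strip()).group(1)
            fields = dict(re.findall(r"(\w+)=\s*(\S+)", header))
            alength = int(fields.get("alength", 4))
            if alength != 4:
                raise ValueError(f"{path}: motif {name!r}: alphabet length {alength} != 4")
            width = int(fields["w"]) if "w" in fields else None
            i += 1
            rows: list[list[float]] = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or _MOTIF_RE.match(stripped) or stripped.startswith("URL"):
                    break
                parts = stripped.split()
                if len(parts) != 4:
                    raise ValueError(
                        f"{path}: motif {name!r} row {len(rows)}: expected 4 columns, got {len(parts)}"
                    )
                rows.append([float(x) for x in parts])
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(
                    f"{path}: motif {name!r}: header says w={width} but found {len(rows)} rows"
                )
            probs = np.array(rows, dtype=float)
            sums = probs.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
            if bad.size:
                raise ValueError(
                    f"{path}: motif {name!r} row {bad[0]} sums to {sums[bad[0]]:.6g}, not 1"
                )
            probs = probs / sums[:, None]
            bg = background if background is not None else (
                file_bg if file_bg is not None else UNIFORM_BACKGROUND
            )
            pwms.append(PWM(name, probs, np.asarray(bg, dtype=float)))
            continue
        i += 1
    if not pwms:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return pwms


def write_pwm_meme(pwms: Sequence[PWM], path: str | Path,
                   background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format (probabilities at full precision)."""
    path = Path(path)
    bg = np.asarray(background if background is not None else pwms[0].background, dtype=float)
    with path.open("w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{x:.12g}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first header cell must be 'id', got {df.columns[0]!r}")
    return df


def read_profile_table(path: str | Path, non_negative: bool = False) -> ProfileSet:
    """Read a TSV whose header row carries axis positions and rows carry tracks."""
    path = Path(path)
    df = _read_tsv(path)
    try:
        axis = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric axis position in header: {exc}") from None
    if axis.size == 0:
        raise ValueError(f"{path}: no axis columns")
    if np.any(np.diff(axis) <= 0):
        raise ValueError(f"{path}: axis positions must be strictly increasing")
    profiles: dict[str, np.ndarray] = {}
    for row_i, row in df.iterrows():
        track = row.iloc[0]
        values = np.empty(axis.size)
        for col_i, cell in enumerate(row.iloc[1:]):
            try:
                values[col_i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {track!r}, column {df.columns[col_i + 1]!r}: {cell!r}"
                ) from None
        if track in profiles:
            raise ValueError(f"{path}: duplicate track id {track!r}")
        profiles[track] = values
    return ProfileSet(axis, profiles, non_negative=non_negative)


def write_profile_table(profiles: ProfileSet, path: str | Path,
                        header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id\t" + "\t".join(repr(float(x)) for x in profiles.axis) + "\n")
        for track, values in profiles.profiles.items():
            fh.write(track + "\t" + "\t".join(repr(float(v)) for v in values) + "\n")


def read_tfbs_map(path: str | Path) -> TFBSMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["crm", "tf", "start", "strand", "score_bits", "q", "length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sites: dict[str, list[TFBS]] = {}
    for row in df.itertuples(index=False):
        sites.setdefault(row.crm, []).append(
            TFBS(
                start=int(row.start),
                tf=str(row.tf),
                strand=str(row.strand),
                score=float(row.score_bits),
                q=float(row.q),
                length=int(row.length),
            )
        )
    return TFBSMap(sites)


def write_tfbs_map(tfbs_map: TFBSMap, path: str | Path,
                   header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("crm\ttf\tstart\tstrand\tscore_bits\tq\tlength\n")
        for crm, sites in tfbs_map.items():
            for s in sites:
                fh.write(
                    f"{crm}\t{s.tf}\t{s.start}\t{s.strand}\t{s.score!r}\t{s.q!r}\t{s.length}\n"
                )


def read_cc_matrix_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a CRM x configuration CC table; returns (crm ids, matrix)."""
    path = Path(path)
    df = _read_tsv(path)
    crms = list(df["id"])
    try:
        cc = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric CC cell: {exc}") from None
    return crms, cc


def write_cc_matrix_table(crms: Sequence[str], cc: np.ndarray, path: str | Path,
                          header_comment: str | None = None) -> None:
    path = Path(path)
    n_cfg = cc.shape[1]
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id\t" + "\t".join(str(k) for k in range(n_cfg)) + "\n")
        for crm, row in zip(crms, cc):
            fh.write(crm + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_pvalue_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format enrichment p-value table.

    Columns: ``id`` (TF), ``comparison``, ``p_act``, ``p_rep``. Blank cells
    mean "not tested" and come back as NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ["id", "comparison", "p_act", "p_rep"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("p_act", "p_rep"):
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# YAML config


def read_yaml(path: str | Path) -> dict:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def write_yaml(data: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(data), sort_keys=False))
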