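"""Metabolic phenotypes: domain types, TSV I/O, and identifier normalization.

A *metabolic phenotype* is a set of metabolite fold-changes (treatment/control
signal-intensity ratios, "SIRs") recorded for one perturbation relative to its
control.  Metabolite identifiers in the wild carry chemical-derivative
decorations (e.g. ``Glycine (3TMS)`` from GC/MS trimethylsilyl derivatives)
and library-specific codes; before two phenotypes can be compared their
identifiers must be normalized and, where possible, resolved to canonical
compound names through a synonym table.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MetaboliteKey",
    "Phenotype",
    "SynonymTable",
    "PhenotypeError",
    "normalize_identifier",
    "read_phenotype",
    "write_phenotype",
    "read_library",
    "load_default_synonyms",
]

logger = logging.getLogger(__name__)

#: Valid fold-change scales for phenotype files.
SCALES = ("ratio", "log2", "log10", "ln")

#: Cap applied to non-positive / non-finite fold changes when ``clamp=True``.
SIR_CLAMP = 1e6


class PhenotypeError(ValueError):
    """Raised for malformed phenotype files or identifiers."""


@dataclass(frozen=True, order=True)
class MetaboliteKey:
    """A normalized metabolite identifier.

    ``canonical`` is the lowercase, derivative-stripped name; ``known`` is
    True when it was resolved through the synonym table and False when the
    normalized raw string was kept as-is (an "unknown" metabolite, matchable
    across phenotypes only by exact normalized string).
    """

    canonical: str
    known: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.canonical:
            raise PhenotypeError("empty metabolite identifier")
        if not self.canonical.islower() and self.canonical.lower() != self.canonical:
            object.__setattr__(self, "canonical", self.canonical.lower())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


class SynonymTable:
    """Mapping from normalized synonyms to canonical compound names.

    Lookup is idempotent: every canonical name maps to itself, so feeding a
    canonical name back through :func:`normalize_identifier` is a fixed point.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if entries:
            for syn, canon in entries.items():
                self.add(syn, canon)

    def add(self, synonym: str, canonical: str) -> None:
        syn = _normalize_text(synonym)
        canon = _normalize_text(canonical)
        if not syn or not canon:
            raise PhenotypeError(f"blank synonym entry: {synonym!r} -> {canonical!r}")
        self._map[syn] = canon
        self._map.setdefault(canon, canon)  # idempotence

    def get(self, normalized: str) -> str | None:
        return self._map.get(normalized)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, normalized: str) -> bool:
        return normalized in self._map

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        """Load a two-column ``synonym<TAB>canonical`` TSV (``#`` comments)."""
        table = cls()
        table.update_from_tsv(path)
        return table

    def update_from_tsv(self, path: str | Path) -> None:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise PhenotypeError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                self.add(parts[0], parts[1])


def load_default_synonyms() -> SynonymTable:
    """The shipped table of ~200 common primary-metabolite synonyms."""
    ref = importlib.resources.files("phenometer").joinpath("data/synonyms.tsv")
    table = SynonymTable()
    with importlib.resources.as_file(ref) as path:
        table.update_from_tsv(path)
    return table


# Derivative tokens introduced by GC/MS sample preparation: trimethylsilyl
# (TMS, possibly with a multiplicity like 3TMS), methoximation (MeOX/MX).
_DERIV_TOKEN = re.compile(r"^\d*\s*(tms|meox|mx)\d*$", re.IGNORECASE)
# Retention-index / library codes: an optional short alpha prefix followed by
# >= 3 digits, e.g. RI1310, RT2040, GMD005, 123456.
_LIB_CODE = re.compile(r"^(ri|rt|idx|lib|mp|gmd)?\d{3,}(\.\d+)?$", re.IGNORECASE)
# Parenthesized/bracketed groups that are pure derivative tags or
# multiplicities, e.g. "(3TMS)", "[2MEOX]", "(2)".
_DERIV_GROUP = re.compile(
    r"[\(\[]\s*(\d*\s*(tms|meox|mx)\d*|\d+)\s*[\)\]]", re.IGNORECASE
)
_DELIMS = re.compile(r"[\s_,;]+")


def _normalize_text(raw: str) -> str:
    """Collapse delimiters to single spaces and lowercase (no token logic)."""
    return _DELIMS.sub(" ", raw).strip().lower()


def normalize_identifier(raw: str, synonyms: SynonymTable) -> MetaboliteKey:
    """Normalize a raw metabolite identifier and resolve it if possible.

    The pipeline is deterministic: trim; drop parenthesized/bracketed
    derivative tags; drop trailing standalone derivative tokens (TMS, MeOX,
    MX, with optional multiplicity) and trailing retention-index/library
    codes; collapse whitespace and ``_,;`` to single spaces; lowercase; then
    look the result up in the synonym table.  On a hit the canonical name is
    returned with ``known=True``; on a miss the normalized string itself is
    kept with ``known=False``.

    Hyphens are *not* delimiters, so chemical names like
    ``glucose-6-phosphate`` survive intact.
    """
    if not raw or not raw.strip():
        raise PhenotypeError("empty metabolite identifier")
    text = _DERIV_GROUP.sub(" ", raw.strip())
    tokens = [t for t in _DELIMS.split(text) if t]
    # Strip derivative / library-code tokens from the tail only, so internal
    # tokens of genuinely unknown peak tags are preserved.
    while tokens and (_DERIV_TOKEN.match(tokens[-1]) or _LIB_CODE.match(tokens[-1])):
        tokens.pop()
    if not tokens:
        # e.g. an identifier that was nothing but a derivative tag
        fallback = _normalize_text(raw)
        if not fallback:
            raise PhenotypeError(f"identifier {raw!r} is empty after normalization")
        tokens = fallback.split(" ")
    normalized = " ".join(tokens).lower()
    canonical = synonyms.get(normalized)
    if canonical is not None:
        return MetaboliteKey(canonical, known=True)
    return MetaboliteKey(normalized, known=False)


@dataclass
class Phenotype:
    """A named metabolic phenotype: metabolite -> SIR fold-change.

    All SIRs are finite and strictly positive (log-scale inputs are
    exponentiated on ingest; non-positive ratios are dropped or clamped).
    """

    id: str
    responses: dict[MetaboliteKey, float] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, sir in self.responses.items():
            if not (math.isfinite(sir) and sir > 0):
                raise PhenotypeError(
                    f"phenotype {self.id!r}: SIR for {key.canonical!r} is {sir!r}; "
                    "must be finite and > 0"
                )

    def __len__(self) -> int:
        return len(self.responses)

    def metabolites(self, unknowns: str = "keep") -> set[MetaboliteKey]:
        """Metabolite keys, optionally excluding unresolved ("unknown") ones."""
        if unknowns == "drop":
            return {k for k in self.responses if k.known}
        return set(self.responses)


def _to_ratio(value: float, scale: str) -> float:
    if scale == "ratio":
        return value
    if scale == "log2":
        return 2.0**value
    if scale == "log10":
        return 10.0**value
    if scale == "ln":
        return math.exp(value)
    raise PhenotypeError(f"unknown scale {scale!r}; expected one of {SCALES}")


def _abs_rv(sir: float) -> float:
    # |RV| without importing simstats (avoids a circular import).
    return sir - 1.0 if sir >= 1.0 else 1.0 / sir - 1.0


def read_phenotype(
    path: str | Path,
    scale: str = "ratio",
    synonyms: SynonymTable | None = None,
    *,
    clamp: bool = False,
    phenotype_id: str | None = None,
) -> Phenotype:
    """Read one phenotype from the TSV dialect.

    The file is UTF-8 with header ``metabolite<TAB>fold_change[<TAB>pvalue]``
    and ``#`` comment lines.  ``scale`` must be declared explicitly; log-scale
    values are exponentiated to ratios.  Any p-value column is stashed in
    ``metadata["pvalues"]`` (JSON) and never used by scoring.

    Rows with SIR <= 0 or non-finite values are dropped with a warning, or
    capped at 10**±6 when ``clamp=True``.  Duplicate metabolites (after
    normalization) keep the row with the largest absolute response value.
    """
    if scale not in SCALES:
        raise PhenotypeError(f"unknown scale {scale!r}; expected one of {SCALES}")
    path = Path(path)
    synonyms = synonyms if synonyms is not None else SynonymTable()
    responses: dict[MetaboliteKey, float] = {}
    pvalues: dict[str, float] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[0].strip().lower() != "metabolite":
                    raise PhenotypeError(
                        f"{path}:{lineno}: expected header starting with 'metabolite'"
                    )
                header_seen = True
                continue
            if len(parts) < 2:
                raise PhenotypeError(f"{path}:{lineno}: expected >= 2 columns")
            key = normalize_identifier(parts[0], synonyms)
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise PhenotypeError(
                    f"{path}:{lineno}: non-numeric fold-change {parts[1]!r}"
                ) from exc
            if not math.isfinite(value) or (scale == "ratio" and value <= 0):
                if clamp:
                    if scale == "ratio":
                        sir = SIR_CLAMP if value > 1 else 1.0 / SIR_CLAMP
                    else:
                        sir = SIR_CLAMP if value > 0 else 1.0 / SIR_CLAMP
                    logger.warning(
                        "read_phenotype: %s:%d value=%r clamped to %g", path, lineno, value, sir
                    )
                else:
                    logger.warning(
                        "read_phenotype: %s:%d dropped row %r (value=%r not a valid SIR)",
                        path, lineno, parts[0], value,
                    )
                    continue
            else:
                sir = _to_ratio(value, scale)
            if not (math.isfinite(sir) and sir > 0):
                logger.warning(
                    "read_phenotype: %s:%d dropped row %r (SIR=%r after scale conversion)",
                    path, lineno, parts[0], sir,
                )
                continue
            if key in responses:
                logger.warning(
                    "read_phenotype: %s:%d duplicate metabolite %r; keeping larger |RV|",
                    path, lineno, key.canonical,
                )
                if _abs_rv(sir) <= _abs_rv(responses[key]):
                    continue
            responses[key] = sir
            if len(parts) >= 3 and parts[2].strip():
                try:
                    pvalues[key.canonical] = float(parts[2])
                except ValueError:
                    pass
    if not header_seen:
        raise PhenotypeError(f"{path}: missing header line")
    metadata: dict[str, str] = {"source": str(path), "scale": scale}
    if pvalues:
        metadata["pvalues"] = json.dumps(pvalues, sort_keys=True)
    pid = phenotype_id if phenotype_id is not None else path.stem
    return Phenotype(id=pid, responses=responses, metadata=metadata)


def write_phenotype(phenotype: Phenotype, path: str | Path) -> Path:
    """Write a phenotype in the TSV dialect (ratio scale, full precision).

    Round-trips bit-compatibly through :func:`read_phenotype` at
    ``scale="ratio"`` via ``repr`` of the float column.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# phenotype: {phenotype.id}\n")
        for k in sorted(phenotype.metadata):
            if k != "pvalues":
                fh.write(f"# {k}: {phenotype.metadata[k]}\n")
        fh.write("metabolite\tfold_change\n")
        for key in sorted(phenotype.responses):
            fh.write(f"{key.canonical}\t{phenotype.responses[key]!r}\n")
    return path


def read_library(
    path: str | Path,
    scale: str = "ratio",
    synonyms: SynonymTable | None = None,
    *,
    clamp: bool = False,
    metadata_path: str | Path | None = None,
) -> list[Phenotype]:
    """Read a reference library of phenotypes.

    ``path`` is either a directory of phenotype TSVs (phenotype id = filename
    stem) or a single long-format TSV with header
    ``phenotype_id<TAB>metabolite<TAB>fold_change``.  An optional metadata TSV
    keyed by ``phenotype_id`` attaches free-form study metadata.
    """
    path = Path(path)
    synonyms = synonyms if synonyms is not None else SynonymTable()
    phenotypes: list[Phenotype]
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tsv", ".txt"))
        if not files:
            raise PhenotypeError(f"{path}: no phenotype TSV files found")
        phenotypes = [
            read_phenotype(p, scale=scale, synonyms=synonyms, clamp=clamp) for p in files
        ]
    else:
        phenotypes = _read_long_format(path, scale, synonyms, clamp=clamp)
    if metadata_path is not None:
        meta = _read_metadata_table(metadata_path)
        for p in phenotypes:
            p.metadata.update(meta.get(p.id, {}))
    return phenotypes


def _read_long_format(
    path: Path, scale: str, synonyms: SynonymTable, *, clamp: bool
) -> list[Phenotype]:
    import tempfile

    groups: dict[str, list[str]] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[0].strip().lower() != "phenotype_id":
                    raise PhenotypeError(
                        f"{path}:{lineno}: expected long-format header starting with 'phenotype_id'"
                    )
                header_seen = True
                continue
            if len(parts) < 3:
                raise PhenotypeError(f"{path}:{lineno}: expected 3 columns")
            groups.setdefault(parts[0], []).append("\t".join(parts[1:3]))
    if not header_seen:
        raise PhenotypeError(f"{path}: missing header line")
    phenotypes = []
    # Reuse read_phenotype row handling by materialising per-phenotype blocks.
    with tempfile.TemporaryDirectory() as tmp:
        for pid in sorted(groups):
            block = Path(tmp) / f"{pid}.tsv"
            block.write_text(
                "metabolite\tfold_change\n" + "\n".join(groups[pid]) + "\n",
                encoding="utf-8",
            )
            p = read_phenotype(block, scale=scale, synonyms=synonyms, clamp=clamp,
                               phenotype_id=pid)
            p.metadata["source"] = str(path)
            phenotypes.append(p)
    return phenotypes


def _read_metadata_table(path: str | Path) -> dict[str, dict[str, str]]:
    import csv

    out: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or "phenotype_id" not in reader.fieldnames:
            raise PhenotypeError(f"{path}: metadata TSV needs a 'phenotype_id' column")
        for row in reader:
            pid = row.pop("phenotype_id")
            out[pid] = {k: v for k, v in row.items() if v not in (None, "")}
    return out
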