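"""File formats: molecules, fingerprint JSON-lines, run configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from rdkit import Chem

from .fingerprint import SVMF, SVMFConfig, _default_h2
from .matching import MoleculeRecord

logger = logging.getLogger(__name__)

_SMILES_EXTENSIONS = {".smi", ".cxsmi", ".smiles", ".txt"}
_SDF_EXTENSIONS = {".sdf", ".mol", ".mdl"}


class FormatError(ValueError):
    pass


def read_molecules(
    path: str | Path, fmt: str | None = None
) -> list[MoleculeRecord]:
    """Read molecules from a SMILES/CXSMILES list or an SDF/MOL file.

    SMILES files carry one record per line with an optional
    tab-separated id (line number otherwise).  SDF records keep their
    2D coordinates.  Unparseable records are skipped with a warning;
    zero parsed records is an error.
    """
    records, skipped = read_molecules_with_stats(path, fmt)
    if skipped:
        logger.warning("%s: skipped %d unparseable record(s)", path, skipped)
    return records


def read_molecules_with_stats(
    path: str | Path, fmt: str | None = None
) -> tuple[list[MoleculeRecord], int]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in _SMILES_EXTENSIONS:
            fmt = "smiles"
        elif suffix in _SDF_EXTENSIONS:
            fmt = "sdf"
        else:
            raise FormatError(
                f"unrecognized extension {suffix!r}; pass fmt='smiles' or "
                "'sdf'"
            )
    if fmt == "smiles":
        records, skipped = _read_smiles_file(path)
    elif fmt == "sdf":
        records, skipped = _read_sdf_file(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if not records:
        raise FormatError(f"{path}: no molecule parsed")
    return records, skipped


def _read_smiles_file(path: Path) -> tuple[list[MoleculeRecord], int]:
    records: list[MoleculeRecord] = []
    skipped = 0
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            text, _, mol_id = line.partition("\t")
            mol_id = mol_id.strip() or str(lineno)
            try:
                records.append(MoleculeRecord.from_smiles(text.strip(), mol_id))
            except ValueError:
                logger.warning("%s:%d: unparseable SMILES", path, lineno)
                skipped += 1
    return records, skipped


def _read_sdf_file(path: Path) -> tuple[list[MoleculeRecord], int]:
    records: list[MoleculeRecord] = []
    skipped = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for pos, mol in enumerate(supplier, start=1):
        if mol is None:
            logger.warning("%s: record %d failed to parse", path, pos)
            skipped += 1
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(MoleculeRecord.from_rdkit(mol, mol_id or str(pos)))
    return records, skipped


def write_fingerprints(
    path: str | Path, items: Iterable[tuple[str, SVMF]]
) -> None:
    """Write fingerprints as JSON-lines; values keep full precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for mol_id, fp in items:
            record = {"id": mol_id, "n": fp.n, "entries": fp.flatten()}
            handle.write(json.dumps(record) + "\n")


def read_fingerprints(path: str | Path) -> list[tuple[str, SVMF]]:
    path = Path(path)
    out: list[tuple[str, SVMF]] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                fp = SVMF.unflatten(
                    record["n"],
                    [(int(i), float(v)) for i, v in record["entries"]],
                )
                out.append((str(record["id"]), fp))
            except (KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"{path}:{lineno}: bad record ({exc})")
    return out


@dataclass
class RunConfig:
    """Configuration for a pipeline run, loadable from YAML."""

    vocabulary: str | None = None  # path; None = shipped default
    h1: float = 10.0
    h2_table: dict[int, float] = field(default_factory=_default_h2)
    d_max: int = 4
    backbone_factor: float = 0.5
    n_slots: int | None = None
    mode: str = "topological"
    expansion_fraction: float = 0.10
    seed: int = 0
    output: str | None = None
    log_level: str = "INFO"

    def svmf_config(self) -> SVMFConfig:
        return SVMFConfig(
            h1=self.h1,
            h2_table=dict(self.h2_table),
            d_max=self.d_max,
            backbone_factor=self.backbone_factor,
            n_slots=self.n_slots,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys."""
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "h2_table" in data:
        data["h2_table"] = {int(k): float(v) for k, v in data["h2_table"].items()}
    cfg = RunConfig(**data)
    if cfg.vocabulary is not None and not Path(cfg.vocabulary).exists():
        raise FormatError(f"vocabulary file not found: {cfg.vocabulary}")
    if cfg.mode not in ("topological", "geometric"):
        raise FormatError(f"unknown mode {cfg.mode!r}")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        yaml.safe_dump(cfg.to_dict(), handle, sort_keys=True)
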