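"""Turn designs into deliverable sequences and reports.

Ships the four published vaccine-candidate substitution sets (α-SC3, α-SC6,
α-SC8, α-SC9) as verbatim data presets, applies designs to scaffold
sequences, and renders byte-stable JSON / FASTA / TSV reports.
"""

from __future__ import annotations

import hashlib
import json
import os
import unicodedata
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Optional

from .fibril_geometry import HelicalParameters
from .graft_design import ConstructDesign, GraftScore, Substitution, ValidationReport
from .structure_io import SequenceRecord, write_fasta
from .surface_analysis import ExposureProfile

__all__ = [
    "PresetRegistry",
    "UnknownPresetError",
    "load_preset",
    "preset_names",
    "apply_design",
    "design_checksum",
    "render_report",
    "load_design_json",
]


class UnknownPresetError(KeyError):
    """Requested preset name is not in the registry."""


def _normalize_name(name: str) -> str:
    name = unicodedata.normalize("NFKC", name)
    name = name.replace("α", "alpha").replace("‐", "-").replace("‑", "-")
    name = name.replace("_", "-").replace(" ", "-").lower()
    while "--" in name:
        name = name.replace("--", "-")
    return name


class PresetRegistry:
    """The packaged, read-only registry of published designs."""

    def __init__(self) -> None:
        raw = json.loads(
            resources.files("betagraft.data").joinpath("presets.json").read_text()
        )
        self.source: str = raw["source"]
        self.scaffold_id: str = raw["scaffold_id"]
        self.rung_offset: int = raw["rung_offset"]
        self._entries: dict[str, dict] = raw["entries"]
        self._aliases = {_normalize_name(k): k for k in self._entries}

    def names(self) -> list[str]:
        return sorted(self._entries)

    def load(self, name: str) -> ConstructDesign:
        key = self._aliases.get(_normalize_name(name))
        if key is None:
            raise UnknownPresetError(
                f"unknown preset {name!r}; available: {', '.join(self.names())}"
            )
        entry = self._entries[key]
        substitutions = tuple(
            Substitution.parse(label, rung=1) for label in entry["rung1"]
        ) + tuple(Substitution.parse(label, rung=2) for label in entry["rung2"])
        return ConstructDesign(
            name=key,
            scaffold_id=self.scaffold_id,
            substitutions=substitutions,
            provenance={
                "donor_id": entry["donor_id"],
                "donor_method": entry["donor_method"],
                "rung_offset": self.rung_offset,
                "source": self.source,
                "note": entry["note"],
            },
        )


_REGISTRY: Optional[PresetRegistry] = None


def _registry() -> PresetRegistry:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = PresetRegistry()
    return _REGISTRY


def preset_names() -> list[str]:
    return _registry().names()


def load_preset(name: str) -> ConstructDesign:
    """Load a published design by name.

    Naming is forgiving: ``alpha-SC9``, ``α-SC9``, ``ALPHA_SC9`` all resolve
    to the same entry.  Returns an immutable design carrying the printed
    substitution list verbatim (anomalies included; run ``validate_design``
    to surface them).
    """
    return _registry().load(name)


# ---------------------------------------------------------------------------
# sequence editing
# ---------------------------------------------------------------------------

def apply_design(
    seq: SequenceRecord,
    design: ConstructDesign,
    strict: bool = True,
) -> SequenceRecord:
    """Apply a design's substitutions to a scaffold sequence.

    Strict mode (default) requires every stored wild-type letter to match
    the sequence; this surfaces numbering conflicts instead of hiding them.
    Non-strict mode applies the new letters regardless and leaves the
    discrepancies to ``validate_design``.  Output keeps length and
    numbering; there are no indels anywhere in this system.
    """
    letters = list(seq.sequence)
    for s in design.substitutions:
        if not (seq.start_number <= s.position <= seq.end_number):
            raise ValueError(
                f"substitution {s.label} outside sequence "
                f"{seq.start_number}-{seq.end_number}"
            )
        idx = s.position - seq.start_number
        if strict and letters[idx] != s.wt:
            raise ValueError(
                f"wild-type mismatch at {s.position}: design expects {s.wt}, "
                f"sequence has {letters[idx]} (use strict=False to override)"
            )
        letters[idx] = s.new
    return SequenceRecord(
        id=f"{seq.id}|{design.name}",
        sequence="".join(letters),
        start_number=seq.start_number,
    )


def design_checksum(design: ConstructDesign) -> str:
    """Stable short checksum of a design's substitution content."""
    canon = design.name + "|" + ",".join(
        f"{s.rung}:{s.label}" for s in sorted(design.substitutions,
                                              key=lambda s: (s.rung, s.position))
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _design_to_dict(design: ConstructDesign) -> dict:
    return {
        "name": design.name,
        "scaffold_id": design.scaffold_id,
        "substitutions": [
            {"position": s.position, "wt": s.wt, "new": s.new, "rung": s.rung}
            for s in design.substitutions
        ],
        "provenance": design.provenance,
        "score": asdict(design.score) if design.score is not None else None,
        "checksum": design_checksum(design),
    }


def load_design_json(path: str | os.PathLike) -> ConstructDesign:
    """Load a design back from a rendered JSON report."""
    raw = json.loads(Path(path).read_text())
    if "design" in raw:
        raw = raw["design"]
    substitutions = tuple(
        Substitution(
            position=s["position"], wt=s["wt"], new=s["new"], rung=s["rung"]
        )
        for s in raw["substitutions"]
    )
    score = GraftScore(**raw["score"]) if raw.get("score") else None
    return ConstructDesign(
        name=raw["name"],
        scaffold_id=raw["scaffold_id"],
        substitutions=substitutions,
        provenance=raw.get("provenance", {}),
        score=score,
    )


def render_report(
    design: ConstructDesign,
    scaffold_seq: Optional[SequenceRecord] = None,
    geometry: Optional[HelicalParameters] = None,
    exposure: Optional[ExposureProfile] = None,
    validation: Optional[ValidationReport] = None,
    out_dir: str | os.PathLike = ".",
    strict: bool = True,
) -> dict[str, Path]:
    """Write the design report bundle; returns the paths written.

    Produces ``<name>.json`` (design, provenance, scores, validation flags,
    geometry summary), ``<name>.tsv`` (position, wt, new, rung), and -- when
    a scaffold sequence is given -- ``<name>.fasta`` with the wild-type and
    mutant sequences.  Output is byte-stable for identical inputs (sorted
    keys, no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = _normalize_name(design.name)
    paths: dict[str, Path] = {}

    payload: dict = {"design": _design_to_dict(design)}
    if geometry is not None:
        payload["geometry"] = {
            "rise": geometry.rise,
            "twist": geometry.twist,
            "rmsd": geometry.rmsd,
            "repeat_kind": geometry.repeat_kind,
        }
    if exposure is not None and exposure.classes:
        payload["exposure"] = {
            f"{c}:{r}": exposure.classes[(c, r)]
            for (c, r) in sorted(exposure.classes)
        }
    if validation is not None:
        payload["validation"] = {
            "clean": validation.clean,
            "wt_mismatches": list(validation.wt_mismatches),
            "asymmetries": list(validation.asymmetries),
            "out_of_range": list(validation.out_of_range),
        }
    json_path = out / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["json"] = json_path

    tsv_path = out / f"{stem}.tsv"
    rows = ["position\twt\tnew\trung"]
    rows += [f"{s.position}\t{s.wt}\t{s.new}\t{s.rung}" for s in design.substitutions]
    tsv_path.write_text("\n".join(rows) + "\n")
    paths["tsv"] = tsv_path

    if scaffold_seq is not None:
        mutant = apply_design(scaffold_seq, design, strict=strict)
        checksum = design_checksum(design)
        fasta_path = out / f"{stem}.fasta"
        write_fasta(
            [
                SequenceRecord(
                    id=f"{scaffold_seq.id}|wild-type",
                    sequence=scaffold_seq.sequence,
                    start_number=scaffold_seq.start_number,
                ),
                SequenceRecord(
                    id=f"{design.name}|{design.scaffold_id}"
                    f"|n_sub={len(design.substitutions)}|sha={checksum}",
                    sequence=mutant.sequence,
                    start_number=mutant.start_number,
                ),
            ],
            fasta_path,
        )
        paths["fasta"] = fasta_path
    return paths
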