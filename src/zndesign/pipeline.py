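"""End-to-end orchestration: mine -> assemble -> screen -> export.

Configuration mirrors the design protocol's parameters (donor-distance
cutoff, interior-length range, binding-site window, top-k alignments,
terminal-coil allowance) and every run is deterministic for a given
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import assembly, mining
from .assembly import AssembledPeptide
from .geometry import evaluate_site, passes_window
from .secstruct import assign_ss, dedup_sequences, terminal_helix_filter
from .structure import Structure, read_structure, write_fasta, write_structure

__all__ = ["DesignConfig", "PipelineReport", "run_pipeline", "load_structures"]

logger = logging.getLogger("zndesign")


@dataclass
class DesignConfig:
    """Tunable parameters of the design pipeline (lengths in Angstrom)."""

    max_donor_distance_A: float = 6.5
    n_interior_min: int = 2
    n_interior_max: int = 20
    site_window_A: tuple[float, float] = (1.5, 5.5)
    top_k_alignments: int = 10
    max_terminal_coil: int = 4
    require_c2h2: bool = True
    exclude_interior_hc: bool = False
    anchor_merge_rmsd_A: float = 0.5
    final_merge_rmsd_A: float = 1.0
    reject_clashes: bool = False
    clash_distance_A: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.site_window_A = tuple(self.site_window_A)  # type: ignore[assignment]
        problems = []
        if self.max_donor_distance_A <= 0:
            problems.append("max_donor_distance_A must be positive")
        if not (0 < self.n_interior_min <= self.n_interior_max):
            problems.append("need 0 < n_interior_min <= n_interior_max")
        lo, hi = self.site_window_A
        if not (0 < lo < hi):
            problems.append("site_window_A must be an increasing positive pair")
        if self.top_k_alignments < 1:
            problems.append("top_k_alignments must be >= 1")
        if self.max_terminal_coil < 0:
            problems.append("max_terminal_coil must be >= 0")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @property
    def n_range(self) -> tuple[int, int]:
        return (self.n_interior_min, self.n_interior_max)

    @classmethod
    def from_yaml(cls, text: str) -> "DesignConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


@dataclass
class PipelineReport:
    """Per-stage candidate counts and the surviving designs."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    designs: list[AssembledPeptide] = field(default_factory=list)
    config: DesignConfig | None = None

    def to_manifest(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "designs": [
                {
                    "index": i,
                    "sequence": d.sequence,
                    "anchors": list(d.anchor_positions),
                    "provenance": d.design_id,
                    "total_merge_rmsd": round(d.total_merge_rmsd, 6),
                }
                for i, d in enumerate(self.designs)
            ],
            "config": dataclasses.asdict(self.config) if self.config else None,
        }


def load_structures(paths: Iterable[str | Path]) -> list[Structure]:
    out = []
    for path in paths:
        path = Path(path)
        out.append(read_structure(path.read_text(), source_id=path.stem))
    return out


def run_pipeline(
    structures: Sequence[Structure],
    config: DesignConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Run the full design protocol over parsed structures.

    Stages: fragment mining -> two-stage assembly -> binding-site window
    and composition screen -> terminal-helix screen -> sequence dedup ->
    optional export (PDB per design, FASTA, TSV, JSON manifest).
    """
    cfg = config or DesignConfig()
    report = PipelineReport(config=cfg)
    t0 = time.perf_counter()

    if structures:
        library = mining.build_library(
            structures,
            max_donor_distance=cfg.max_donor_distance_A,
            n_range=cfg.n_range,
            exclude_interior_hc=cfg.exclude_interior_hc,
        )
    else:
        library = mining.FragmentLibrary()
    report.stage_counts["structures"] = len(structures)
    report.stage_counts["fragments"] = len(library)
    logger.info("mined %d fragments from %d structures", len(library), len(structures))

    candidates = assembly.assemble_candidates(
        library,
        k=cfg.top_k_alignments,
        anchor_merge_rmsd=cfg.anchor_merge_rmsd_A,
        final_merge_rmsd=cfg.final_merge_rmsd_A,
    ) if len(library) else []
    report.stage_counts["assembled"] = len(candidates)
    logger.info("assembled %d four-anchor candidates", len(candidates))

    sited = []
    for pep in candidates:
        ok, _ = passes_window(
            evaluate_site(pep), window=cfg.site_window_A, require_c2h2=cfg.require_c2h2
        )
        if ok and (
            not cfg.reject_clashes
            or not assembly.has_steric_clash(pep, cutoff=cfg.clash_distance_A)
        ):
            sited.append(pep)
    report.stage_counts["site_pass"] = len(sited)
    logger.info("%d candidates pass the binding-site screen", len(sited))

    helical = [
        pep
        for pep in sited
        if terminal_helix_filter(assign_ss(pep), max_terminal_coil=cfg.max_terminal_coil)
    ]
    report.stage_counts["ss_pass"] = len(helical)
    logger.info("%d candidates pass the terminal-helix screen", len(helical))

    unique = dedup_sequences(helical)
    report.stage_counts["unique"] = len(unique)
    report.designs = unique
    logger.info(
        "%d unique designs (%.2f s total)", len(unique), time.perf_counter() - t0
    )

    if outdir is not None:
        export_report(report, outdir)
    return report


def export_report(report: PipelineReport, outdir: str | Path) -> None:
    """Write designs (PDB + FASTA + TSV) and the JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_records = []
    rows = []
    for i, pep in enumerate(report.designs):
        name = f"design_{i:03d}"
        st = Structure(source_id=name)
        from .structure import Chain

        st.chains.append(Chain(chain_id="A", residues=pep.residues))
        (outdir / f"{name}.pdb").write_text(write_structure(st))
        fasta_records.append((f"{name} anchors={pep.anchor_positions} {pep.design_id}", pep.sequence))
        site = evaluate_site(pep)
        rows.append(
            {
                "design": name,
                "sequence": pep.sequence,
                "anchors": "+".join(map(str, pep.anchor_positions)),
                "composition": site.composition,
                "total_merge_rmsd": round(pep.total_merge_rmsd, 4),
                **{
                    f"d{i+1}{j+1}": round(dist, 3)
                    for (i, j), dist in zip(
                        [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
                        site.pairwise_distances,
                    )
                },
            }
        )
    (outdir / "designs.fasta").write_text(write_fasta(fasta_records) if fasta_records else "")
    pd.DataFrame(rows).to_csv(outdir / "designs.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(report.to_manifest(), indent=2, sort_keys=True) + "\n"
    )
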