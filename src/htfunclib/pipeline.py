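"""End-to-end orchestration: configuration, pipeline runs and demo fixtures.

``run_design`` chains the stages — conservation profile, pocket
neighborhoods, single-mutation energy scan, threshold selection,
neighborhood enumeration and scoring, EpiNNet training and ranking, library
selection and in-silico validation — and writes every artifact plus a run
manifest that makes the run reproducible.

``make_fixture`` writes fully synthetic demo inputs (a toy barrel-like PDB
with a central ligand, a gapped homolog alignment, a planted-incompatibility
energy landscape, sorted/presorted count tables, a two-island fitness
landscape) together with ground-truth files that only tests read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energy import (
    SyntheticLandscape,
    ddg_scan,
    filter_by_ddg,
    generate_landscape,
    read_scan_tsv,
    write_scan_tsv,
)
from .epinnet import (
    LibraryDefinition,
    NeighborhoodSample,
    SiteNeighborhood,
    assemble_dataset,
    enumerate_neighborhood,
    library_resfile_block,
    rank_mutations,
    read_library_tsv,
    select_ddg_threshold,
    select_library,
    space_size,
    train_epinnet,
    validate_spaces,
    write_library_tsv,
)
from .genotypes import AMINO_ACIDS, Genotype
from .landscape import (
    GenotypeSpace,
    build_landscape_model,
    region_logos,
    write_coordinates_tsv,
)
from .pocket import (
    Neighborhood,
    build_neighborhoods,
    ligand_shell,
    parse_structure,
    relative_sasa,
    write_neighborhoods,
    write_sasa_table,
)
from .profiles import build_pssm, pssm_allowed_mutations, read_alignment, write_pssm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of a design run, with field-standard defaults."""

    structure_path: str = ""
    ligand_name: str = "CRO"
    chain: str = "A"
    msa_path: str = ""
    reference_id: str = "ref"
    landscape_path: str = ""  # synthetic landscape JSON (energy oracle)
    scan_path: str = ""  # optional external ddG scan TSV
    designed_positions: list[int] = field(default_factory=list)
    pssm_threshold: float = -2.0
    contact_cutoff: float = 6.0
    min_atom_pairs: int = 2
    shell_cutoff: float = 8.0
    ddg_grid: list[float] = field(
        default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0, 5.5, 6.0]
    )
    max_total: int = 1_000_000
    threshold_mode: str = "total"
    full_limit: int = 10_000
    sample_fraction: float = 0.1
    target_size: int = 4_000_000
    enrichment_threshold: float = 1.0
    target_occupancy: float = 0.6
    n_axes: int = 2
    validation_n: int = 10_000
    exhaustive_limit: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def require(self, *names: str) -> None:
        for name in names:
            if not getattr(self, name):
                raise ValueError(f"config field {name!r} is required but empty")


def to_site_neighborhoods(
    neighborhoods: Sequence[Neighborhood], chain: str
) -> list[SiteNeighborhood]:
    """Project structural (chain, resnum) neighborhoods onto residue numbers."""
    out = []
    for nb in neighborhoods:
        if any(c != chain for c, _ in nb.members):
            raise ValueError(f"neighborhood {nb.center} spans chains other than {chain}")
        out.append(SiteNeighborhood(nb.center[1], tuple(n for _, n in nb.members)))
    return out


def run_design(config: RunConfig, out_dir) -> tuple[LibraryDefinition, dict]:
    """Execute the full library-design pipeline and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    def register(name: str, path: Path) -> Path:
        manifest["outputs"][name] = str(path)
        return path

    # --- stage: conservation profile -------------------------------------
    config.require("msa_path", "structure_path", "landscape_path")
    aln = read_alignment(config.msa_path, config.reference_id)
    pssm = build_pssm(aln)
    designed = sorted(config.designed_positions)
    if not designed:
        raise ValueError("config field 'designed_positions' is required but empty")
    pssm_allowed = pssm_allowed_mutations(pssm, designed, config.pssm_threshold)
    write_pssm(pssm, register("pssm", out / "pssm.tsv"))
    manifest["stages"]["profiles"] = {
        "n_sequences": len(aln.sequences),
        "n_positions": len(pssm.positions),
    }

    # --- stage: pocket neighborhoods --------------------------------------
    structure = parse_structure(config.structure_path, config.ligand_name)
    shell = ligand_shell(structure, config.shell_cutoff)
    designed_pos = [(config.chain, p) for p in designed]
    outside = [p for p in designed_pos if p not in shell]
    if outside:
        logger.warning("designed positions outside the ligand shell: %s", outside)
    neighborhoods = build_neighborhoods(
        structure, designed_pos, config.contact_cutoff, config.min_atom_pairs
    )
    site_nbhds = to_site_neighborhoods(neighborhoods, config.chain)
    write_neighborhoods(neighborhoods, register("neighborhoods", out / "neighborhoods.json"))
    sasa = relative_sasa(structure)
    write_sasa_table(sasa, register("sasa", out / "sasa.tsv"))
    manifest["stages"]["pocket"] = {
        "n_neighborhoods": len(neighborhoods),
        "shell_size": len(shell),
    }

    # --- stage: energy scan ------------------------------------------------
    oracle = SyntheticLandscape.from_json(config.landscape_path)
    reference = {p: oracle.reference[p] for p in designed}
    if config.scan_path:
        scan = read_scan_tsv(config.scan_path)
    else:
        candidates = {
            p: set(pssm_allowed[p]) & set(oracle.allowed[p]) for p in designed
        }
        scan = ddg_scan(oracle, reference, candidates)
    write_scan_tsv(scan, register("scan", out / "scan.tsv"), chain=config.chain)
    threshold, size_table = select_ddg_threshold(
        site_nbhds, scan, config.ddg_grid, config.max_total, config.threshold_mode
    )
    size_table.to_csv(register("threshold_table", out / "threshold_table.tsv"),
                      sep="\t", index=False)
    tolerated = filter_by_ddg(scan, threshold)
    manifest["stages"]["energy"] = {
        "n_scanned": len(scan),
        "ddg_threshold": threshold,
        "n_tolerated": int(sum(len(v) for v in tolerated.values())),
    }

    # --- stage: EpiNNet ----------------------------------------------------
    samples = []
    for nb in site_nbhds:
        genos = enumerate_neighborhood(
            nb, tolerated, reference, config.full_limit,
            config.sample_fraction, config.seed,
        )
        energies = np.array([oracle.energy(g) for g in genos])
        samples.append(NeighborhoodSample(nb, genos, energies))
    dataset = assemble_dataset(samples, tolerated, reference)
    model = train_epinnet(dataset, seed=config.seed)
    ranked = rank_mutations(model, tolerated, reference, scan)
    library, trace = select_library(ranked, reference, config.target_size)
    write_library_tsv(library, register("library", out / "library.tsv"))
    (out / "library.resfile").write_text(library_resfile_block(library, config.chain))
    register("resfile", out / "library.resfile")
    pd.DataFrame(
        [(str(m), int(s)) for m, s in trace], columns=["mutation", "space_size"]
    ).to_csv(register("trace", out / "trace.tsv"), sep="\t", index=False)

    filtered_lib = LibraryDefinition(
        allowed={
            p: frozenset(tolerated.get(p, set()) | {reference[p]}) for p in designed
        },
        reference=reference,
    )
    report = validate_spaces(
        oracle, library, filtered_lib,
        n=config.validation_n, seed=config.seed,
        exhaustive_limit=config.exhaustive_limit,
    )
    with open(register("validation", out / "validation.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    manifest["stages"]["epinnet"] = {
        "n_training_rows": int(len(dataset.y)),
        "holdout_accuracy": model.holdout_accuracy,
        "n_ranked": len(ranked),
        "library_space": space_size(library),
    }

    with open(register("manifest", out / "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return library, report


def run_landscape(
    config: RunConfig, library_path, labels_path, out_dir,
    logo_axis: int = 1, logo_thresholds: Sequence[float] = (),
) -> None:
    """Build the evolutionary model over a library space from functional calls.

    ``labels_path`` is a TSV with columns genotype (identity string over the
    library's positions, sorted) and functional (0/1).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib = read_library_tsv(library_path)
    space = GenotypeSpace.from_allowed(lib.allowed)
    if space.size > 200_000:
        raise ValueError(
            f"genotype space of {space.size} exceeds the desk-scale cap; "
            "restrict the library before visualizing"
        )
    calls = pd.read_csv(labels_path, sep="\t", dtype={"genotype": str})
    lut = dict(zip(calls["genotype"], calls["functional"].astype(int)))
    f = np.array([lut.get(g.to_string(), 0) for g in space.genotypes()])
    model = build_landscape_model(
        space, f, target_occupancy=config.target_occupancy, k=config.n_axes
    )
    write_coordinates_tsv(model, out / "coordinates.tsv")
    if logo_thresholds:
        logos = region_logos(
            model.coordinates, space.genotypes(), logo_axis - 1,
            logo_thresholds, mask=f.astype(bool),
        )
        for i, logo in enumerate(logos):
            logo.to_csv(out / f"logo_region{i + 1}.tsv", sep="\t")
    with open(out / "landscape_manifest.json", "w") as fh:
        json.dump(
            {
                "c": model.c,
                "n_genotypes": space.size,
                "n_functional": int(f.sum()),
                "eigenvalues": model.eigenvalues.tolist(),
                "version": __version__,
            },
            fh,
            indent=1,
        )


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

_RING_RESNAMES = ["ALA", "LEU", "SER", "VAL", "THR", "ILE", "PHE", "MET",
                  "ASN", "GLN", "LYS", "GLU"]


def _pdb_atom_line(serial, name, resname, chain, resnum, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_toy_barrel_pdb(
    path, n_ring: int = 10, ring_radius: float = 7.0, ligand_name: str = "CRO"
) -> list[int]:
    """Write a synthetic barrel-like PDB: a residue ring around a central ligand.

    Purely geometric stand-in for a real structure: residues at positions
    1..n_ring on chain A form a ring with side chains pointing inward toward
    the ligand at the origin; residue n_ring+1 sits inside the barrel
    (buried).  Returns the ring residue numbers.
    """
    lines = ["HEADER    SYNTHETIC TOY BARREL"]
    serial = 1
    for i in range(n_ring):
        theta = 2 * math.pi * i / n_ring
        resnum = i + 1
        resname = _RING_RESNAMES[i % len(_RING_RESNAMES)]
        cx, cy = ring_radius * math.cos(theta), ring_radius * math.sin(theta)
        bx, by = (ring_radius - 1.8) * math.cos(theta), (ring_radius - 1.8) * math.sin(theta)
        atoms = [
            ("N", cx, cy, 1.2, "N"),
            ("CA", cx, cy, 0.0, "C"),
            ("C", cx, cy, -1.2, "C"),
            ("O", cx + 0.6, cy + 0.6, -1.9, "O"),
            ("CB", bx, by, 0.0, "C"),
        ]
        for name, x, y, z, el in atoms:
            lines.append(_pdb_atom_line(serial, name, resname, "A", resnum, x, y, z, el))
            serial += 1
    # buried residue just off-center inside the barrel
    buried_num = n_ring + 1
    for name, x, y, z, el in [
        ("N", 2.2, 0.0, 1.2, "N"),
        ("CA", 2.2, 0.0, 0.0, "C"),
        ("C", 2.2, 0.0, -1.2, "C"),
        ("O", 2.8, 0.6, -1.9, "O"),
        ("CB", 3.2, 0.8, 0.0, "C"),
    ]:
        lines.append(_pdb_atom_line(serial, name, "VAL", "A", buried_num, x, y, z, el))
        serial += 1
    # three-atom ligand at the origin
    for name, x, y, z, el in [("C1", 0.0, 0.0, 0.0, "C"),
                              ("N1", -1.0, 0.5, 0.0, "N"),
                              ("O1", 1.0, 0.5, 0.0, "O")]:
        lines.append(
            "HETATM" + _pdb_atom_line(serial, name, ligand_name, "A", buried_num + 1,
                                      x, y, z, el)[6:]
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return list(range(1, n_ring + 1))


def make_demo_msa(
    path,
    reference_seq: str,
    variable_positions: Sequence[int] = (),
    n_alternates: int = 3,
    n_homologs: int = 60,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Write a gapped FASTA alignment with a known per-column identity profile.

    Columns at ``variable_positions`` (1-based) draw the reference identity
    with probability 0.4 and each of ``n_alternates`` alternates with equal
    probability, frequencies comfortably above the -2 bit conservation
    threshold; every other column is fully conserved.  A few homologs carry a
    gapped tail column.  Returns the planted identity sets per variable
    position (reference included).
    """
    rng = np.random.default_rng(seed)
    variable = set(variable_positions)
    alternates: dict[int, list[str]] = {}
    for pos in sorted(variable):
        ref_aa = reference_seq[pos - 1]
        pool = [aa for aa in AMINO_ACIDS if aa != ref_aa]
        alternates[pos] = sorted(
            rng.choice(pool, size=n_alternates, replace=False).tolist()
        )
    records = [(">ref", reference_seq)]
    for h in range(n_homologs):
        chars = []
        for i, aa in enumerate(reference_seq):
            pos = i + 1
            if pos in variable and rng.random() > 0.4:
                chars.append(alternates[pos][rng.integers(n_alternates)])
            else:
                chars.append(aa)
        if h % 5 == 0:  # a few homologs with a gapped tail column
            chars[-1] = "-"
        records.append((f">homolog_{h}", "".join(chars)))
    Path(path).write_text("\n".join(f"{h}\n{s}" for h, s in records) + "\n")
    return {
        pos: sorted({reference_seq[pos - 1], *alts})
        for pos, alts in alternates.items()
    }


def make_fixture(kind: str, seed: int, out_dir) -> dict:
    """Write synthetic demo inputs plus ground truth (tests only) to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "design-demo":
        return _make_design_demo(out, seed)
    if kind == "counts-demo":
        return _make_counts_demo(out, seed)
    if kind == "two-island":
        return _make_two_island(out, seed)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _make_design_demo(out: Path, seed: int) -> dict:
    ring = make_toy_barrel_pdb(out / "structure.pdb")
    designed = ring[:6]

    # reference sequence long enough to cover the ring positions
    rng = np.random.default_rng(seed)
    ref_seq = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(12))
    make_demo_msa(out / "msa.fasta", ref_seq, variable_positions=designed, seed=seed)

    aln = read_alignment(out / "msa.fasta", "ref")
    pssm = build_pssm(aln)
    write_pssm(pssm, out / "pssm_ground_truth.tsv")
    allowed_by_pssm = pssm_allowed_mutations(pssm, designed, -2.0)

    reference = {p: ref_seq[p - 1] for p in designed}
    # the landscape's alphabet is exactly the conservation-tolerated space
    allowed = {p: set(allowed_by_pssm[p]) - {reference[p]} for p in designed}
    structure = parse_structure(out / "structure.pdb", "CRO")
    nbhds = build_neighborhoods(structure, [("A", p) for p in designed])
    contacts = sorted(
        {
            (min(nb.center[1], m[1]), max(nb.center[1], m[1]))
            for nb in nbhds
            for m in nb.members[1:]
        }
    )
    oracle = generate_landscape(
        reference, allowed, contacts,
        field_scale=1.0, coupling_scale=0.25,
        n_incompatible_pairs=2, incompatible_penalty=10.0, seed=seed,
    )
    oracle.to_json(out / "landscape.json")

    config = RunConfig(
        structure_path=str(out / "structure.pdb"),
        msa_path=str(out / "msa.fasta"),
        landscape_path=str(out / "landscape.json"),
        designed_positions=designed,
        ddg_grid=[0.5, 1.0, 1.5, 2.0, 3.0],
        target_size=100,
        validation_n=2000,
        exhaustive_limit=5000,
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    truth = {
        "designed_positions": designed,
        "planted_pairs": [
            [list(a), list(b)] for a, b in oracle.planted_pairs
        ],
        "reference": reference,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _make_counts_demo(out: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    positions = [1, 2, 3, 4]
    reference = {1: "A", 2: "C", 3: "D", 4: "E"}
    alleles = {1: "AG", 2: "CW", 3: "DH", 4: "EK"}
    space = GenotypeSpace.from_allowed(alleles)
    genos = space.genotypes()
    names = [g.to_string() for g in genos]

    labels = {}
    rows = []
    presorted_count = 1000
    for name in names:
        gate_hits = []
        for gate in ("GFP", "AmCyan"):
            enriched = rng.random() < 0.3
            # enrichment = (sorted_freq / presorted_freq); totals are equal by
            # construction, so count ratios carry the signal with wide margins
            sorted_count = presorted_count * (4 if enriched else 1) // (1 if enriched else 4)
            rows.append((name, f"sorted_{gate}", sorted_count))
            if enriched:
                gate_hits.append(gate)
        rows.append((name, "presorted", presorted_count))
        labels[name] = (
            "both" if len(gate_hits) == 2 else gate_hits[0] if gate_hits
            else "nonfunctional"
        )
    pd.DataFrame(rows, columns=["genotype", "sample", "count"]).to_csv(
        out / "counts.tsv", sep="\t", index=False
    )
    truth = {"labels": labels, "positions": positions, "reference": reference}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _make_two_island(out: Path, seed: int) -> dict:
    positions = [1, 2, 3]
    alleles = {p: "ACDE" for p in positions}
    space = GenotypeSpace.from_allowed(alleles)
    islands = {}
    functional = []
    for g in space.genotypes():
        ids = [aa for _, aa in g.identities]
        if all(aa in "AC" for aa in ids):
            islands[g.to_string()] = 1
            functional.append(1)
        elif all(aa in "DE" for aa in ids):
            islands[g.to_string()] = 2
            functional.append(1)
        else:
            islands[g.to_string()] = 0
            functional.append(0)
    frame = pd.DataFrame(
        {
            "genotype": [g.to_string() for g in space.genotypes()],
            "functional": functional,
            "island": [islands[g.to_string()] for g in space.genotypes()],
        }
    )
    frame[["genotype", "functional"]].to_csv(out / "labels.tsv", sep="\t", index=False)
    lib_rows = [(p, "A", "ACDE") for p in positions]
    pd.DataFrame(lib_rows, columns=["position", "reference", "allowed"]).to_csv(
        out / "library.tsv", sep="\t", index=False
    )
    truth = {"islands": islands}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
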