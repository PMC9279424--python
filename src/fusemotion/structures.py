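"""Atomic-structure I/O, domain selection, and residue correspondences.

Structures are flat ordered lists of atom records addressed exclusively by
author residue numbering (chain id, residue number, insertion code), the
numbering convention in which all domain boundaries of the fusogen constructs
are stated.  Reading and writing of PDB/mmCIF goes through :mod:`gemmi`;
sequence alignment for cross-structure correspondences goes through
:mod:`Bio.Align`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np
import yaml
from Bio import Align

from .errors import (
    CorrespondenceError,
    EmptyStructureError,
    FormatError,
    SelectionError,
)

ResidueKey = tuple[str, int, str]  # (chain_id, residue_number, insertion_code)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom in author numbering, coordinates in Å."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    occupancy: float
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed position for {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclasses.dataclass
class Structure:
    """Ordered atom list with a human-readable label."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def ca_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.atom_name == "CA" and a.element != "CA"]

    def ca_coords(self) -> np.ndarray:
        cas = self.ca_atoms()
        if not cas:
            raise EmptyStructureError(f"structure {self.label!r} has no Cα atoms")
        return np.array([a.position for a in cas], dtype=float)

    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys of Cα-bearing residues, in atom order."""
        seen: dict[ResidueKey, None] = {}
        for a in self.ca_atoms():
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def ca_lookup(self) -> dict[ResidueKey, np.ndarray]:
        return {a.residue_key: a.position for a in self.ca_atoms()}

    def element_symbols(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclasses.dataclass(frozen=True)
class DomainDefinition:
    """Named set of inclusive author-numbering residue intervals.

    The canonical fusogen domain names (D1, D2.1, D2.2, D3, the fusion loops
    FL1/2/3, the J0 strand) are just labels; any name is accepted.
    """

    name: str
    intervals: tuple[tuple[str, int, int], ...]  # (chain, start, end), inclusive

    def __post_init__(self) -> None:
        ivals = tuple((str(c), int(s), int(e)) for c, s, e in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        for chain, start, end in ivals:
            if start > end:
                raise ValueError(f"{self.name}: interval start {start} > end {end}")
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, start, end in ivals:
            by_chain.setdefault(chain, []).append((start, end))
        for chain, spans in by_chain.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.name}: overlapping intervals {s1}-{e1} and {s2}-{e2} on chain {chain}"
                    )

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return any(
            chain_id == chain and start <= residue_number <= end
            for chain, start, end in self.intervals
        )


@dataclasses.dataclass(frozen=True)
class ResidueCorrespondence:
    """One-to-one pairing of residues between two structures."""

    pairs: tuple[tuple[ResidueKey, ResidueKey], ...]
    mode: Literal["identity", "sequence-alignment", "user-table"]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise CorrespondenceError("empty residue correspondence")
        a_keys = [p[0] for p in self.pairs]
        b_keys = [p[1] for p in self.pairs]
        if len(set(a_keys)) != len(a_keys) or len(set(b_keys)) != len(b_keys):
            raise CorrespondenceError("correspondence is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def paired_ca_coords(
        self, a: Structure, b: Structure
    ) -> tuple[np.ndarray, np.ndarray]:
        """Cα coordinate arrays (n, 3) for the pairs resolvable in both."""
        ca_a = a.ca_lookup()
        ca_b = b.ca_lookup()
        xs, ys = [], []
        for ka, kb in self.pairs:
            if ka in ca_a and kb in ca_b:
                xs.append(ca_a[ka])
                ys.append(ca_b[kb])
        if not xs:
            raise CorrespondenceError("no correspondence pair resolves to Cα in both structures")
        return np.array(xs), np.array(ys)


def _norm_key(chain: str, num: int, icode: str) -> ResidueKey:
    return (chain, num, icode.strip())


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    include_waters: bool = False,
    include_hydrogens: bool = False,
    label: str | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is used.  For alternate locations the
    highest-occupancy conformer is kept; ties break toward the first altloc
    in file order.  Waters and hydrogens are dropped unless requested.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    # altloc resolution: best occupancy per (chain, residue, atom name)
    best: dict[tuple[ResidueKey, str], AtomRecord] = {}
    order: list[tuple[ResidueKey, str]] = []
    for chain in model:
        for res in chain:
            if not include_waters and res.name in _WATER_NAMES:
                continue
            key_res = _norm_key(chain.name, res.seqid.num, res.seqid.icode)
            for atom in res:
                elem = atom.element.name
                if not include_hydrogens and elem in ("H", "D"):
                    continue
                rec = AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=elem,
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
                k = (key_res, atom.name)
                if k not in best:
                    best[k] = rec
                    order.append(k)
                elif rec.occupancy > best[k].occupancy:
                    best[k] = rec
    atoms = [best[k] for k in order]
    if not atoms:
        raise EmptyStructureError(f"{path}: model contains no usable atoms")
    return Structure(atoms=atoms, label=label or path.stem)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a structure as a PDB file (coordinates at 0.001 Å precision)."""
    st = gemmi.Structure()
    st.name = s.label or "fusemotion"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: tuple[str, int, str] | None = None
    res: gemmi.Residue | None = None
    for a in s.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
            model.add_chain(chains[a.chain_id])
            current = None
        if current != (a.chain_id, a.residue_number, a.insertion_code):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            # gemmi copies on add; re-fetch the live residue
            chain = model[a.chain_id]
            chain.add_residue(res)
            res = chain[len(chain) - 1]
            current = (a.chain_id, a.residue_number, a.insertion_code)
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.occ = a.occupancy
        atom.pos = gemmi.Position(*a.position)
        res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def select_domain(
    s: Structure,
    d: DomainDefinition,
    atom_filter: Literal["CA-only", "all-atoms"] = "all-atoms",
) -> Structure:
    """Atoms of ``s`` falling in the intervals of ``d``, order preserved."""
    atoms = [a for a in s.atoms if d.contains(a.chain_id, a.residue_number)]
    if atom_filter == "CA-only":
        atoms = [a for a in atoms if a.atom_name == "CA" and a.element != "CA"]
    elif atom_filter != "all-atoms":
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    if not atoms:
        raise SelectionError(f"domain {d.name!r} selects no atoms in {s.label!r}")
    return Structure(atoms=atoms, label=f"{s.label}:{d.name}")


_aligner_cache: dict[tuple[float, float, float], Align.PairwiseAligner] = {}


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _chain_sequence(s: Structure, chain_id: str) -> tuple[str, list[ResidueKey]]:
    keys = [k for k in s.residue_keys() if k[0] == chain_id]
    lookup = {a.residue_key: a.residue_name for a in s.ca_atoms()}
    seq = "".join(_one_letter(lookup[k]) for k in keys)
    return seq, keys


def build_correspondence(
    a: Structure,
    b: Structure,
    mode: Literal["identity", "sequence-alignment", "user-table"] = "identity",
    pairs: Sequence[tuple[ResidueKey, ResidueKey]] | None = None,
    match_score: float = 1.0,
    mismatch_score: float = -1.0,
    gap_score: float = -2.0,
) -> ResidueCorrespondence:
    """Establish a one-to-one residue pairing between two structures.

    ``identity`` intersects (chain, residue number, insertion code) keys;
    ``sequence-alignment`` globally aligns per-chain one-letter sequences
    (linear gap penalty) and pairs aligned non-gap columns; ``user-table``
    passes ``pairs`` through (e.g. a correspondence exported from a
    structure-alignment program).
    """
    if mode == "user-table":
        if not pairs:
            raise CorrespondenceError("user-table mode requires explicit pairs")
        return ResidueCorrespondence(pairs=tuple(pairs), mode="user-table")

    if mode == "identity":
        keys_b = set(b.residue_keys())
        common = [(k, k) for k in a.residue_keys() if k in keys_b]
        if not common:
            raise CorrespondenceError(
                f"no shared residue keys between {a.label!r} and {b.label!r}"
            )
        return ResidueCorrespondence(pairs=tuple(common), mode="identity")

    if mode != "sequence-alignment":
        raise ValueError(f"unknown correspondence mode {mode!r}")

    chains_a = list(dict.fromkeys(k[0] for k in a.residue_keys()))
    chains_b = list(dict.fromkeys(k[0] for k in b.residue_keys()))
    shared = [c for c in chains_a if c in chains_b]
    chain_pairs = (
        [(c, c) for c in shared] if shared else list(zip(chains_a, chains_b))
    )

    key = (match_score, mismatch_score, gap_score)
    aligner = _aligner_cache.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match_score
        aligner.mismatch_score = mismatch_score
        aligner.open_gap_score = gap_score
        aligner.extend_gap_score = gap_score
        _aligner_cache[key] = aligner

    out: list[tuple[ResidueKey, ResidueKey]] = []
    for ca, cb in chain_pairs:
        seq_a, keys_a = _chain_sequence(a, ca)
        seq_b, keys_b2 = _chain_sequence(b, cb)
        if not seq_a or not seq_b:
            continue
        alignment = aligner.align(seq_a, seq_b)[0]
        for (sa, ea), (sb, _eb) in zip(*alignment.aligned):
            for off in range(ea - sa):
                out.append((keys_a[sa + off], keys_b2[sb + off]))
    if not out:
        raise CorrespondenceError(
            f"sequence alignment of {a.label!r} vs {b.label!r} produced no pairs"
        )
    return ResidueCorrespondence(pairs=tuple(out), mode="sequence-alignment")


def load_domain_definitions(path: str | Path) -> dict[str, DomainDefinition]:
    """Load domain definitions from a YAML file.

    Schema: ``domains: [{name, chain, start, end}, ...]`` where a name may
    recur to declare multi-interval domains, or a top-level list of the same
    mappings.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("domains", doc) if isinstance(doc, dict) else doc
    if not isinstance(entries, list):
        raise FormatError(f"{path}: expected a list of domain mappings")
    grouped: dict[str, list[tuple[str, int, int]]] = {}
    for e in entries:
        try:
            grouped.setdefault(str(e["name"]), []).append(
                (str(e.get("chain", "A")), int(e["start"]), int(e["end"]))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad domain entry {e!r}: {exc}") from exc
    return {
        name: DomainDefinition(name=name, intervals=tuple(ivals))
        for name, ivals in grouped.items()
    }


def default_domain_definitions(chain: str = "A") -> dict[str, DomainDefinition]:
    """Fusogen ectodomain domain boundaries in author numbering.

    The ectodomain spans residues 28–564 and the D1D2 construct 28–457, so D3
    is taken to start at 458.  The D1/D2 and D2.1/D2.2 boundaries are not
    fixed by the construct definitions and ship as placeholders; override via
    a YAML config for real analyses.
    """
    mk = lambda name, *ivals: DomainDefinition(name, tuple((chain, s, e) for s, e in ivals))
    return {
        "ectodomain": mk("ectodomain", (28, 564)),
        "D1D2": mk("D1D2", (28, 457)),
        "D3": mk("D3", (458, 564)),
        # placeholder split of D1D2; user-overridable
        "D1": mk("D1", (28, 130), (446, 457)),
        "D2": mk("D2", (131, 445)),
        "D2.1": mk("D2.1", (131, 170), (240, 445)),
        "D2.2": mk("D2.2", (171, 239)),
        "FL1": mk("FL1", (190, 198)),
        "FL2": mk("FL2", (209, 214)),
        "FL3": mk("FL3", (143, 149)),
        "J0": mk("J0", (447, 456)),
    }
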