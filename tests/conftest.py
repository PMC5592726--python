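"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately use plain Python double loops and no
code from the package's contact modules, so they stay an independent
check on the vectorized implementations.
"""

from __future__ import annotations

import math

import pytest

from gpcreval.structure_model import (
    BACKBONE_ATOMS,
    ContactThresholds,
    StructureModel,
    VdwTable,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a.coords, b.coords)))


def oracle_min_distance(res_a, res_b, sidechain_only: bool = False) -> float:
    best = float("inf")
    for a in res_a.atoms:
        if a.is_hydrogen or (sidechain_only and a.name in BACKBONE_ATOMS):
            continue
        for b in res_b.atoms:
            if b.is_hydrogen or (sidechain_only and b.name in BACKBONE_ATOMS):
                continue
            best = min(best, dist(a, b))
    return best


def oracle_ligand_contacts(s: StructureModel, ligand, cutoff: float) -> set:
    """Residue ids within the cutoff of any ligand heavy atom (pure distance rule)."""
    out = set()
    for res in s.residues:
        best = float("inf")
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            for b in ligand.atoms:
                if b.is_hydrogen:
                    continue
                best = min(best, dist(a, b))
        if best < cutoff:
            out.add(res.rid)
    return out


def oracle_contact_map(s: StructureModel, vdw: VdwTable, t: ContactThresholds) -> set:
    """All side-chain residue pairs under the vdW-sum rule, O(N^2 A^2)."""
    pairs = set()
    residues = s.residues
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            if ri.chain == rj.chain and abs(ri.seqnum - rj.seqnum) < t.min_seq_separation:
                continue
            hit = False
            for a in ri.atoms:
                if a.is_hydrogen or a.name in BACKBONE_ATOMS:
                    continue
                for b in rj.atoms:
                    if b.is_hydrogen or b.name in BACKBONE_ATOMS:
                        continue
                    if dist(a, b) < vdw.radius(a) + vdw.radius(b) + t.vdw_tolerance:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add(frozenset((ri.rid, rj.rid)))
    return pairs


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def thresholds() -> ContactThresholds:
    return ContactThresholds()


@pytest.fixture(scope="session")
def vdw() -> VdwTable:
    return VdwTable()


@pytest.fixture(scope="session")
def default_complex():
    """One parsed synthetic complex with all four interaction types planted."""
    from gpcreval.structure_model import parse_structure
    from gpcreval.synthetic_data import gen_bundle_complex

    pdb_text, descriptor, truth = gen_bundle_complex(
        seed=11,
        n_contacts_per_label={
            "hbond": 1, "salt_bridge": 1, "aromatic_stacking": 1, "hydrophobic": 1
        },
        n_decoys=6,
    )
    structure = parse_structure(pdb_text, structure_id="default-complex")
    return structure, descriptor, truth


@pytest.fixture(scope="session")
def synth_numbering():
    from gpcreval.synthetic_data import synthetic_numbering

    return synthetic_numbering()
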