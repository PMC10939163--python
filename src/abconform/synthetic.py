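"""Self-contained synthetic inputs for every pipeline stage.

Generates Martin-numbered two-chain Fv-like entries whose CDR backbones
are built from planted torsion clusters, with controllable bound/unbound
change modes (none, AP-cluster shift, canonical-cluster shift, novel
conformation, rigid "flapping") and injectable quality defects
(resolution, B-factor, missing residues/domains, cis non-prolines,
framework deformation), plus a ground-truth manifest for recovery
scoring.

Backbones are placed sequentially from ideal peptide geometry (NeRF), so
measuring dihedrals on a built chain recovers the inputs.  The framework
is a fixed idealized scaffold shared by all entries; each CDR (and the
single framework residue that follows it, which defines the loop's final
psi) is re-placed by NeRF continuation from the N-side anchor.  The chain
is deliberately left open at that point: loop closure is NOT enforced,
which no downstream stage requires, and the torsion code treats the long
C-N junction as a chain break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import (
    CDR_RANGES,
    Atom,
    AntibodyEntry,
    Residue,
    ResidueID,
    write_entry,
)

__all__ = [
    "BOND_N_CA",
    "BOND_CA_C",
    "BOND_C_N",
    "ClusterSpec",
    "CohortConfig",
    "CohortResult",
    "PERTURBATION_MODES",
    "place_atom",
    "build_backbone",
    "wrap_angle",
    "sample_torsion_cluster",
    "default_cluster_centers",
    "make_entry",
    "generate_flap_pair",
    "generate_cohort",
]

# Ideal peptide backbone geometry (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
# CB placement via the N-C-CA-CB improper dihedral.
BOND_CA_CB = 1.521
ANGLE_C_CA_CB = 110.1
IMPROPER_N_C_CA_CB = 122.55

CHAIN_LENGTHS = {"H": 113, "L": 110}

PERTURBATION_MODES = ("identical", "ap_shift", "canonical_shift", "novel")

DEFECT_KINDS = (
    "resolution",
    "missing_domain",
    "missing_residue",
    "bfactor",
    "cis_nonproline",
    "framework_shift",
)


def wrap_angle(deg):
    """Wrap degrees into (-180, 180]."""
    wrapped = -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)
    return wrapped


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from a-b-c internal coords.

    The returned point is at distance ``bond`` from c, makes angle
    ``angle_deg`` (b-c-d) and dihedral ``torsion_deg`` (a-b-c-d).
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(
    torsions: Sequence[tuple[float, float, float]],
) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C coordinates from per-residue (phi, psi, omega).

    phi of the first residue and omega of the first residue are unused
    (undefined at a chain start); psi of the last residue is unused
    because no following nitrogen is placed.
    """
    n_res = len(torsions)
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        _, psi_prev, _ = torsions[i - 1]
        phi_i, _, omega_i = torsions[i]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, omega_i)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    return coords


def _cb_position(res: dict[str, np.ndarray]) -> np.ndarray:
    return place_atom(
        res["N"], res["C"], res["CA"], BOND_CA_CB, ANGLE_C_CA_CB, IMPROPER_N_C_CA_CB
    )


@dataclass
class ClusterSpec:
    """A planted torsion cluster: per-residue (phi, psi) centers + spread."""

    center: np.ndarray  # (L, 2) degrees
    spread: float  # wrapped-normal s.d., degrees
    n_members: int = 0
    cis_positions: list[int] = field(default_factory=list)  # 0-based loop indices

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.spread < 0:
            raise ValueError("spread must be non-negative")


def sample_torsion_cluster(
    spec: ClusterSpec, rng: np.random.Generator, n: Optional[int] = None
) -> np.ndarray:
    """Draw (n, L, 2) phi/psi samples from a wrapped normal around the centers."""
    n = spec.n_members if n is None else n
    noise = rng.normal(0.0, spec.spread, size=(n, *spec.center.shape))
    return wrap_angle(spec.center[None] + noise)


# ---------------------------------------------------------------------------
# Fv scaffold and entry construction
# ---------------------------------------------------------------------------

_REGIONS = [(-65.0, -40.0), (-120.0, 135.0), (-75.0, -20.0), (-140.0, 150.0)]


def _framework_torsion(i: int) -> tuple[float, float, float]:
    # Alternate extended and helical stretches so chains fold up and
    # frameworks are far from collinear.
    phi, psi = _REGIONS[1] if (i // 8) % 2 == 0 else _REGIONS[0]
    return (phi, psi, 180.0)


_SCAFFOLD_CACHE: dict[str, list[dict[str, np.ndarray]]] = {}


def _chain_scaffold(chain: str) -> list[dict[str, np.ndarray]]:
    if chain not in _SCAFFOLD_CACHE:
        n = CHAIN_LENGTHS[chain]
        torsions = [_framework_torsion(i) for i in range(n)]
        coords = build_backbone(torsions)
        if chain == "H":  # keep the two chains apart in space
            coords = [
                {k: v + np.array([60.0, 0.0, 0.0]) for k, v in r.items()}
                for r in coords
            ]
        _SCAFFOLD_CACHE[chain] = coords
    return _SCAFFOLD_CACHE[chain]


_AA_ALPHABET = "ACDEFHIKLMNQRSTVWY"  # no P (cis bookkeeping), no G (keeps CB)


def _chain_sequence(chain: str, ab_idx: int, cis_by_cdr: dict[str, list[int]]) -> list[str]:
    """Deterministic per-antibody sequence; CDRs mix A/S/G, cis sites get P."""
    n = CHAIN_LENGTHS[chain]
    seq = ["S" if (i % 7) == 3 else "A" for i in range(n)]
    # encode the antibody index so distinct antibodies have distinct sequences
    code = ab_idx
    for pos in range(4, 10):
        seq[pos] = _AA_ALPHABET[code % len(_AA_ALPHABET)]
        code //= len(_AA_ALPHABET)
    for cdr, (ch, start, end) in CDR_RANGES.items():
        if ch != chain:
            continue
        for k in range(end - start + 1):
            seq[start - 1 + k] = "ASG"[k % 3]
        for k in cis_by_cdr.get(cdr, []):
            seq[start - 1 + k] = "P"
    return seq


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def make_entry(
    pdb_code: str,
    index: int,
    antigen_type: Optional[str],
    ab_idx: int,
    cdr_torsions: dict[str, np.ndarray],
    cdr_omegas: Optional[dict[str, np.ndarray]] = None,
    resolution: Optional[float] = 2.0,
    b_factor: float = 20.0,
    flap: Optional[dict[str, float]] = None,
    framework_noise: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    drop_residues: Sequence[tuple[str, int]] = (),
    bfactor_overrides: Sequence[tuple[str, int, float]] = (),
    drop_chain: Optional[str] = None,
    cis_to_proline: bool = True,
) -> AntibodyEntry:
    """Build one synthetic Fv entry.

    ``cdr_torsions`` maps CDR name to an (L, 2) array of planted (phi, psi)
    degrees; ``cdr_omegas`` optionally overrides the all-trans omegas (0 at
    an index makes that peptide bond cis).  ``flap`` maps CDR name to a
    rigid rotation angle (degrees) applied about the anchor-to-anchor axis
    after building, preserving internal loop geometry exactly.  Defect
    hooks: ``framework_noise`` perturbs framework atoms (Angstrom s.d.),
    ``drop_residues`` removes (chain, number), ``bfactor_overrides`` sets
    the CA B-factor of (chain, number), ``drop_chain`` omits a chain.
    """
    cdr_omegas = cdr_omegas or {}
    # cis positions become prolines by default; disable to plant a cis
    # non-proline defect without changing the sequence
    cis_by_cdr = (
        {
            cdr: [int(i) for i in np.flatnonzero(np.abs(wrap_angle(om)) < 30.0)]
            for cdr, om in cdr_omegas.items()
        }
        if cis_to_proline
        else {}
    )
    chains: dict[str, list[Residue]] = {}
    for chain in ("H", "L"):
        if drop_chain == chain:
            continue
        scaffold = _chain_scaffold(chain)
        coords = [{k: v.copy() for k, v in r.items()} for r in scaffold]
        for cdr in cdr_torsions:
            ch, start, end = CDR_RANGES[cdr]
            if ch != chain:
                continue
            tor = np.asarray(cdr_torsions[cdr], dtype=float)
            L = end - start + 1
            if tor.shape != (L, 2):
                raise ValueError(
                    f"{cdr} torsions must have shape ({L}, 2), got {tor.shape}"
                )
            omegas = np.asarray(
                cdr_omegas.get(cdr, np.full(L, 180.0)), dtype=float
            )
            s = start - 1  # 0-based index of the first CDR residue
            prev = coords[s - 1]
            a, b, c = prev["N"], prev["CA"], prev["C"]
            psi_prev = _framework_torsion(s - 1)[1]
            for k in range(L + 1):
                n_k = place_atom(a, b, c, BOND_C_N, ANGLE_CA_C_N, psi_prev)
                if k == L:
                    # Only the following framework residue's N is continued
                    # (it defines the loop's last psi); its CA/C stay on the
                    # scaffold so the framework is identical across entries.
                    coords[s + k]["N"] = n_k
                    break
                phi_k, psi_k = tor[k]
                ca_k = place_atom(b, c, n_k, BOND_N_CA, ANGLE_C_N_CA, omegas[k])
                c_k = place_atom(c, n_k, ca_k, BOND_CA_C, ANGLE_N_CA_C, phi_k)
                coords[s + k] = {"N": n_k, "CA": ca_k, "C": c_k}
                a, b, c = n_k, ca_k, c_k
                psi_prev = psi_k
            if flap and cdr in flap and flap[cdr] != 0.0:
                pivot = coords[s - 1]["CA"]
                axis = coords[s + L]["CA"] - pivot
                R = _rotation_about_axis(axis, flap[cdr])
                for k in range(L):
                    for name in coords[s + k]:
                        coords[s + k][name] = R @ (coords[s + k][name] - pivot) + pivot

        seq = _chain_sequence(chain, ab_idx, cis_by_cdr)
        in_cdr = np.zeros(len(coords), dtype=bool)
        for cdr, (ch, start, end) in CDR_RANGES.items():
            if ch == chain:
                in_cdr[start - 1 : end] = True
        residues: list[Residue] = []
        for i, rc in enumerate(coords):
            number = i + 1
            if (chain, number) in drop_residues:
                continue
            aa = seq[i]
            atoms = {k: v.copy() for k, v in rc.items()}
            if aa != "G":
                atoms["CB"] = _cb_position(rc)
            if framework_noise and not in_cdr[i]:
                if rng is None:
                    raise ValueError("framework_noise requires an rng")
                for name in atoms:
                    atoms[name] = atoms[name] + rng.normal(0, framework_noise, 3)
            b_by_atom = {name: b_factor for name in atoms}
            for ch_o, num_o, val in bfactor_overrides:
                if ch_o == chain and num_o == number:
                    b_by_atom["CA"] = val
            residues.append(
                Residue(
                    ResidueID(chain, number),
                    aa,
                    {
                        name: Atom(tuple(float(x) for x in xyz), b_by_atom[name], 1.0)
                        for name, xyz in atoms.items()
                    },
                )
            )
        chains[chain] = residues
    return AntibodyEntry(pdb_code, index, antigen_type, chains, resolution)


def generate_flap_pair(
    ab_idx: int,
    cdr: str,
    angle: float,
    seed: int,
    pdb_code: Optional[str] = None,
) -> tuple[AntibodyEntry, AntibodyEntry]:
    """One unbound/bound pair whose only difference is a rigid CDR flap."""
    rng = np.random.default_rng(seed)
    code = pdb_code or f"{8000 + ab_idx % 1000:04d}"
    torsions = {
        name: sample_torsion_cluster(
            ClusterSpec(_center_for_cdr(name, "c1"), 5.0), rng, 1
        )[0]
        for name in CDR_RANGES
    }
    unbound = make_entry(code, 0, None, ab_idx, torsions)
    bound = make_entry(code, 1, "P", ab_idx, torsions, flap={cdr: angle})
    return unbound, bound


# ---------------------------------------------------------------------------
# Planted cluster layout
# ---------------------------------------------------------------------------


def default_cluster_centers(L: int) -> dict[str, np.ndarray]:
    """Torsion-cluster centers for a loop of length L.

    "c1" and "c2" differ by a compensating (psi +60, phi -60) rotation of
    one mid-loop peptide unit: torsionally distant (AP separates them) but
    Cartesian-similar (CartesianCriteria merges them into one canonical
    cluster).  "c3" changes every residue's region: a distinct canonical
    cluster.  "novel" is a positive-phi conformation far from all three.
    """
    c1 = np.array([_REGIONS[i % 3] for i in range(L)], dtype=float)
    c2 = c1.copy()
    k = 1 if L > 2 else 0  # near the N-anchor: smallest Cartesian footprint
    c2[k, 1] += 60.0
    if k + 1 < L:
        c2[k + 1, 0] -= 60.0
    c3 = np.array([_REGIONS[(i + 1) % 4] for i in range(L)], dtype=float)
    novel = np.array([(60.0, 45.0)] * L, dtype=float)
    return {"c1": wrap_angle(c1), "c2": wrap_angle(c2), "c3": c3, "novel": novel}


def _center_for_cdr(cdr: str, which: str) -> np.ndarray:
    _, start, end = CDR_RANGES[cdr]
    return default_cluster_centers(end - start + 1)[which]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Proportions refer to the four bound-vs-unbound change modes.  The
    default within-cluster spread of 2 degrees against >= 60 degree
    center separation is the generator's definition of strong
    separation: loops are built open-chain, so torsional noise is not
    damped by a closure constraint and accumulates into Cartesian
    deviation along the loop; the spread is kept small enough that
    planted clusters stay Cartesian-coherent relative to the 1.0/1.5/1.9
    Angstrom merge thresholds for every CDR length.
    """

    n_antibodies: int = 60
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "identical": 0.6, "ap_shift": 0.2, "canonical_shift": 0.1, "novel": 0.1
        }
    )
    unbound_per_antibody: int = 1
    bound_per_antibody: int = 1
    spread: float = 2.0
    seed: int = 0
    defects: tuple[str, ...] = ()

    def __post_init__(self):
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions must sum to 1, got {total}")
        for k in self.type_proportions:
            if k not in PERTURBATION_MODES:
                raise ValueError(f"unknown mode {k!r}")
        for d in self.defects:
            if d not in DEFECT_KINDS:
                raise ValueError(f"unknown defect {d!r}")


@dataclass
class CohortResult:
    entries: list[AntibodyEntry]
    manifest: pd.DataFrame  # one row per antibody x CDR (+ defect rows)
    files: list[Path] = field(default_factory=list)


def _planted_types(config: CohortConfig) -> list[str]:
    n = config.n_antibodies
    counts = {
        m: int(round(config.type_proportions.get(m, 0.0) * n))
        for m in PERTURBATION_MODES
    }
    # fix rounding drift on the most common mode
    drift = n - sum(counts.values())
    counts["identical"] += drift
    types: list[str] = []
    for m in PERTURBATION_MODES:
        types.extend([m] * counts[m])
    # interleave deterministically so cluster assignment cycles stay balanced
    order = sorted(range(n), key=lambda i: (i * 7919) % n)
    return [types[i] for i in order]


def generate_cohort(
    config: CohortConfig, out_dir: Optional[str | Path] = None
) -> CohortResult:
    """Generate a cohort of unbound/bound Fv entries with a ground-truth manifest.

    Unbound CDR conformations are drawn from planted clusters c1/c2/c3
    (cycling per antibody so all clusters are populated).  Bound
    conformations realize the antibody's planted change mode: exact
    torsion copies for "identical", donor-member copies from the sister /
    distinct cluster for "ap_shift" / "canonical_shift", and a far
    conformation for "novel".  With the same seed the cohort is
    bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_antibodies
    types = _planted_types(config)
    cluster_cycle = ("c1", "c2", "c3")

    # Unbound cluster per antibody: ap_shift antibodies must sit in c1/c2
    # (each other's sister); others cycle all three clusters.
    unbound_cluster: list[str] = []
    for i, t in enumerate(types):
        if t == "ap_shift":
            unbound_cluster.append(("c1", "c2")[i % 2])
        else:
            unbound_cluster.append(cluster_cycle[i % 3])

    cdr_names = sorted(CDR_RANGES)
    centers = {cdr: default_cluster_centers(
        CDR_RANGES[cdr][2] - CDR_RANGES[cdr][1] + 1) for cdr in cdr_names}

    # Planted unbound torsions: antibody -> cdr -> (unbound_per, L, 2)
    unbound_torsions: list[dict[str, np.ndarray]] = []
    for i in range(n):
        per_cdr = {}
        for cdr in cdr_names:
            spec = ClusterSpec(centers[cdr][unbound_cluster[i]], config.spread)
            per_cdr[cdr] = sample_torsion_cluster(
                spec, rng, config.unbound_per_antibody
            )
        unbound_torsions.append(per_cdr)

    def donor(i: int, target: str) -> int:
        for j in range(n):
            if j != i and unbound_cluster[j] == target:
                return j
        raise RuntimeError(f"no donor antibody in cluster {target}")

    entries: list[AntibodyEntry] = []
    manifest_rows: list[dict] = []
    for i in range(n):
        code = f"{9000 + i:04d}"
        mode = types[i]
        for u in range(config.unbound_per_antibody):
            entries.append(
                make_entry(
                    code, u, None, i,
                    {c: unbound_torsions[i][c][u] for c in cdr_names},
                )
            )
        for b in range(config.bound_per_antibody):
            bound_t: dict[str, np.ndarray] = {}
            for cdr in cdr_names:
                if mode == "identical":
                    bound_t[cdr] = unbound_torsions[i][cdr][0]
                elif mode == "ap_shift":
                    sister = "c2" if unbound_cluster[i] == "c1" else "c1"
                    bound_t[cdr] = unbound_torsions[donor(i, sister)][cdr][0]
                elif mode == "canonical_shift":
                    target = "c3" if unbound_cluster[i] != "c3" else "c1"
                    bound_t[cdr] = unbound_torsions[donor(i, target)][cdr][0]
                else:  # novel
                    spec = ClusterSpec(centers[cdr]["novel"], config.spread)
                    bound_t[cdr] = sample_torsion_cluster(spec, rng, 1)[0]
            entries.append(
                make_entry(
                    code, config.unbound_per_antibody + b, "P", i, bound_t
                )
            )
        for cdr in cdr_names:
            manifest_rows.append(
                {
                    "antibody": code,
                    "cdr": cdr,
                    "unbound_cluster": unbound_cluster[i],
                    "planted_type": mode,
                    "defect": "",
                }
            )

    entries.extend(
        _defect_entries(config, centers, cdr_names, manifest_rows, rng)
    )

    manifest = pd.DataFrame(manifest_rows)
    files: list[Path] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for e in entries:
            files.append(write_entry(e, out_dir / f"{e.entry_id}.pdb"))
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return CohortResult(entries, manifest, files)


def _defect_entries(config, centers, cdr_names, manifest_rows, rng):
    """One antibody per requested defect: clean unbound + clean bound + one
    entry carrying the defect, engineered to be rejected at exactly the
    intended filter step."""
    entries: list[AntibodyEntry] = []
    for d_idx, defect in enumerate(config.defects):
        ab_idx = 5000 + d_idx
        code = f"{ab_idx:04d}"
        torsions = {
            cdr: sample_torsion_cluster(
                ClusterSpec(centers[cdr]["c1"], config.spread), rng, 1
            )[0]
            for cdr in cdr_names
        }
        clean_u = make_entry(code, 0, None, ab_idx, torsions)
        clean_b = make_entry(code, 1, "P", ab_idx, torsions)
        if defect == "resolution":
            extra = make_entry(code, 2, "P", ab_idx, torsions, resolution=3.5)
        elif defect == "missing_domain":
            extra = make_entry(code, 2, "P", ab_idx, torsions, drop_chain="L")
        elif defect == "missing_residue":
            extra = make_entry(
                code, 2, "P", ab_idx, torsions, drop_residues=[("H", 52)]
            )
        elif defect == "bfactor":
            extra = make_entry(
                code, 2, "P", ab_idx, torsions, bfactor_overrides=[("H", 97, 85.0)]
            )
        elif defect == "cis_nonproline":
            _, s, e = CDR_RANGES["H2"]
            omegas = np.full(e - s + 1, 180.0)
            omegas[3] = 0.0  # cis at a non-proline CDR position
            extra = make_entry(
                code, 2, None, ab_idx, torsions,
                cdr_omegas={"H2": omegas}, cis_to_proline=False,
            )
        elif defect == "framework_shift":
            extra = make_entry(
                code, 2, None, ab_idx, torsions,
                framework_noise=1.2, rng=rng,
            )
        else:  # pragma: no cover
            raise ValueError(defect)
        entries.extend([clean_u, clean_b, extra])
        manifest_rows.append(
            {
                "antibody": code,
                "cdr": "",
                "unbound_cluster": "",
                "planted_type": "",
                "defect": defect,
            }
        )
    return entries
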