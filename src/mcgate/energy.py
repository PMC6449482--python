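"""Nonbonded energy: Lennard-Jones 6-12 plus Coulomb with a distance-
dependent dielectric, 9 A cutoff with a shifting function, and no cutoff for
pairs of ionized-group atoms.

The dielectric is eps(r) = slope * r (default slope 4), so the Coulomb term
is ``332.06 q_i q_j / (slope r^2)``.  Two shifting modes are available:
``shifted_force`` (energy and derivative vanish at the cutoff; the default,
friendlier to minimization) and ``shifted_energy`` (energy vanishes at the
cutoff).  1-2 and 1-3 bonded pairs are excluded; 1-4 pairs are scaled.

Totals are decomposable per residue pair, which feeds the contact-energy
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COULOMB_CONSTANT = 332.06  # kcal * Angstrom / (mol * e^2)

__all__ = ["NonbondedOptions", "EnergyBreakdown", "pair_energy",
           "nonbonded_energy", "nonbonded_energy_forces", "PairTable",
           "COULOMB_CONSTANT"]


@dataclass(frozen=True)
class NonbondedOptions:
    cutoff: float = 9.0                 # Angstrom; np.inf disables truncation
    dielectric_slope: float = 4.0       # dimensionless per Angstrom
    shift_mode: str = "shifted_force"   # or "shifted_energy"
    ionized_no_cutoff: bool = True
    scale14: float = 0.5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.dielectric_slope <= 0:
            raise ValueError("dielectric_slope must be positive")
        if self.shift_mode not in ("shifted_force", "shifted_energy"):
            raise ValueError(f"unknown shift_mode {self.shift_mode!r}")


@dataclass
class EnergyBreakdown:
    """Total nonbonded energy with per-residue-pair attribution."""

    total: float
    lj: float
    coulomb: float
    restraint: float = 0.0
    per_pair: dict = field(default_factory=dict)   # (key_i, key_j) -> dict

    def pair_total(self, key_i, key_j) -> float:
        key = (key_i, key_j) if key_i <= key_j else (key_j, key_i)
        return self.per_pair.get(key, {}).get("E_total", 0.0)


def _lj_params(eps_i, eps_j, rh_i, rh_j):
    return np.sqrt(eps_i * eps_j), rh_i + rh_j


def _pair_terms(r, eps, rmin, qq, slope):
    """Unshifted LJ and Coulomb energies and radial derivatives."""
    sr = rmin / r
    sr6 = sr ** 6
    e_lj = eps * (sr6 * sr6 - 2.0 * sr6)
    de_lj = eps * 12.0 * (-sr6 * sr6 + sr6) / r
    e_c = COULOMB_CONSTANT * qq / (slope * r * r)
    de_c = -2.0 * e_c / r
    return e_lj, e_c, de_lj, de_c


def pair_energy(atom_i, atom_j, r: float, opts: NonbondedOptions = NonbondedOptions(),
                bonded_separation: int | None = None) -> float:
    """Nonbonded energy of one atom pair at distance ``r`` (kcal/mol).

    ``atom_i``/``atom_j`` carry ``charge``, ``lj_epsilon``, ``lj_rmin_half``
    and ``ionized``.  Pairs where both atoms belong to ionized groups bypass
    the cutoff.  1-2/1-3 pairs are excluded; 1-4 pairs scaled.
    """
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    if bonded_separation is not None and bonded_separation <= 2:
        return 0.0
    scale = opts.scale14 if bonded_separation == 3 else 1.0
    eps, rmin = _lj_params(atom_i.lj_epsilon, atom_j.lj_epsilon,
                           atom_i.lj_rmin_half, atom_j.lj_rmin_half)
    qq = atom_i.charge * atom_j.charge
    ionized = atom_i.ionized and atom_j.ionized
    rc = opts.cutoff
    no_cut = (ionized and opts.ionized_no_cutoff) or not np.isfinite(rc)
    e_lj, e_c, de_lj, de_c = _pair_terms(r, eps, rmin, qq,
                                         opts.dielectric_slope)
    e = e_lj + e_c
    if not no_cut:
        if r >= rc:
            return 0.0
        ec_lj, ec_c, dec_lj, dec_c = _pair_terms(rc, eps, rmin, qq,
                                                 opts.dielectric_slope)
        e -= ec_lj + ec_c
        if opts.shift_mode == "shifted_force":
            e -= (dec_lj + dec_c) * (r - rc)
    return float(scale * e)


class PairTable:
    """Precomputed nonbonded pair list for a system (topology-static)."""

    def __init__(self, system, opts: NonbondedOptions,
                 active_residues=None):
        n = system.n_atoms
        seps = system.bonded_separations(3)
        iu, ju = np.triu_indices(n, k=1)
        scale = np.ones(len(iu))
        drop = np.zeros(len(iu), dtype=bool)
        # closed-form upper-triangle linear index for (a < b)
        def lin(a, b):
            return a * n - a * (a + 1) // 2 + (b - a - 1)

        for (a, b), d in seps.items():
            k = lin(a, b)
            if d <= 2:
                drop[k] = True
            elif d == 3:
                scale[k] = opts.scale14
        if active_residues is not None:
            act = np.zeros(len(system.residues), dtype=bool)
            act[list(active_residues)] = True
            keep_atom = act[system.atom_residue]
            drop |= ~(keep_atom[iu] & keep_atom[ju])
        keep = ~drop
        self.i = iu[keep]
        self.j = ju[keep]
        self.scale = scale[keep]
        self.eps = np.sqrt(system.lj_epsilon[self.i] *
                           system.lj_epsilon[self.j])
        self.rmin = (system.lj_rmin_half[self.i] +
                     system.lj_rmin_half[self.j])
        self.qq = system.charges[self.i] * system.charges[self.j]
        self.ionized = (system.ionized_mask[self.i] &
                        system.ionized_mask[self.j])
        nres = len(system.residues)
        ri = system.atom_residue[self.i]
        rj = system.atom_residue[self.j]
        lo = np.minimum(ri, rj)
        hi = np.maximum(ri, rj)
        self.respair = lo * nres + hi
        self.opts = opts

    def energies(self, X):
        """Per-pair shifted energies (LJ, Coulomb) and radial derivative."""
        opts = self.opts
        d = X[self.i] - X[self.j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        e_lj, e_c, de_lj, de_c = _pair_terms(r, self.eps, self.rmin, self.qq,
                                             opts.dielectric_slope)
        de = de_lj + de_c
        rc = opts.cutoff
        if np.isfinite(rc):
            truncated = ~(self.ionized & opts.ionized_no_cutoff)
            ec_lj, ec_c, dec_lj, dec_c = _pair_terms(
                rc, self.eps, self.rmin, self.qq, opts.dielectric_slope)
            inside = r < rc
            app = truncated & inside
            e_lj = np.where(app, e_lj - ec_lj, e_lj)
            e_c = np.where(app, e_c - ec_c, e_c)
            if opts.shift_mode == "shifted_force":
                shift = (dec_lj + dec_c) * (r - rc)
                # attribute the force-shift term to the LJ column
                e_lj = np.where(app, e_lj - shift, e_lj)
                de = np.where(app, de - (dec_lj + dec_c), de)
            out = truncated & ~inside
            e_lj = np.where(out, 0.0, e_lj)
            e_c = np.where(out, 0.0, e_c)
            de = np.where(out, 0.0, de)
        return e_lj * self.scale, e_c * self.scale, de * self.scale, r, d


def _get_pair_table(system, opts, active_residues=None):
    key = (opts, None if active_residues is None
           else tuple(sorted(active_residues)))
    cache = getattr(system, "_pair_table_cache", None)
    if cache is None:
        cache = system._pair_table_cache = {}
    if key not in cache:
        cache[key] = PairTable(system, opts, active_residues)
    return cache[key]


def nonbonded_energy(system, opts: NonbondedOptions = NonbondedOptions(),
                     group_filter=None, active_residues=None
                     ) -> EnergyBreakdown:
    """Total nonbonded energy with per-residue-pair decomposition.

    ``group_filter`` restricts the reported pairs to those with one residue
    in each of two residue-index sets (the total then equals the sum of the
    filtered per-pair energies).  ``active_residues`` excludes all other
    residues from the computation entirely (double-shell usage).
    """
    system.rebuild()
    table = _get_pair_table(system, opts, active_residues)
    e_lj, e_c, _, r, _ = table.energies(system.cartesian)
    if np.any(r <= 0):
        raise ValueError("coincident atoms in nonbonded computation")
    nres = len(system.residues)
    if group_filter is not None:
        ga, gb = (set(group_filter[0]), set(group_filter[1]))
        if ga & gb:
            raise ValueError("group_filter groups overlap")
        ri = table.respair // nres
        rj = table.respair % nres
        in_a = np.isin(ri, list(ga))
        in_b = np.isin(rj, list(gb))
        in_a2 = np.isin(ri, list(gb))
        in_b2 = np.isin(rj, list(ga))
        mask = (in_a & in_b) | (in_a2 & in_b2)
        e_lj = np.where(mask, e_lj, 0.0)
        e_c = np.where(mask, e_c, 0.0)

    tot = np.bincount(table.respair, weights=e_lj + e_c,
                      minlength=nres * nres)
    lj = np.bincount(table.respair, weights=e_lj, minlength=nres * nres)
    cl = np.bincount(table.respair, weights=e_c, minlength=nres * nres)
    per_pair = {}
    for pid in np.flatnonzero(np.abs(tot) + np.abs(lj) + np.abs(cl) > 0):
        ri, rj = divmod(int(pid), nres)
        a, b = system.residues[ri], system.residues[rj]
        key_a = (system.segments[a.segment_index].id, a.seq_number)
        key_b = (system.segments[b.segment_index].id, b.seq_number)
        per_pair[(key_a, key_b)] = {
            "E_LJ": float(lj[pid]), "E_coul": float(cl[pid]),
            "E_total": float(tot[pid]),
            "residue_indices": (ri, rj),
        }
    return EnergyBreakdown(total=float(e_lj.sum() + e_c.sum()),
                           lj=float(e_lj.sum()), coulomb=float(e_c.sum()),
                           per_pair=per_pair)


def nonbonded_energy_forces(system, opts: NonbondedOptions,
                            active_residues=None):
    """Fast path: total nonbonded energy and per-atom Cartesian gradient."""
    table = _get_pair_table(system, opts, active_residues)
    X = system.cartesian
    e_lj, e_c, de, r, d = table.energies(X)
    g = (de / r)[:, None] * d          # dE/dx_i contribution
    grad = np.zeros_like(X)
    np.add.at(grad, table.i, g)
    np.add.at(grad, table.j, -g)
    return float(e_lj.sum() + e_c.sum()), grad
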