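"""Per-residue auxiliary feature providers.

Several site features come from external tools run offline — PSI-BLAST
position-specific scoring matrices, evolutionary conservation scores,
disorder predictions, DSSP secondary structure and accessibility, and
side-chain energy terms.  This module reads those outputs from files and
supplies documented fallbacks when a file is absent, so the pipeline is
runnable with no external binaries:

* PSSM       → BLOSUM62 row of the residue's amino acid
* C-score    → 0
* disorder   → six zeros
* SS         → coil
* ASA        → internal sphere-sampling accessibility (Shrake–Rupley style,
               960-point unit sphere, probe 1.4 Å)
* SCE terms  → six zeros
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Chain, Complex
from .tables import DEFAULT_VDW, PSSM_ORDER, VDW_RADII, blosum62_row

N_DISORDER = 6
N_SCE = 6
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960

ResKey = tuple[str, int]


def read_psiblast_pssm(text: str) -> list[np.ndarray]:
    """Read the 20 log-odds columns of a PSI-BLAST ASCII PSSM.

    Returns one 20-vector per query residue, in PSI-BLAST column order
    (``ARNDCQEGHILKMFPSTWYV``).
    """
    rows: list[np.ndarray] = []
    for line in text.splitlines():
        parts = line.split()
        # data rows: index, residue letter, 20 log-odds, 20 percentages, ...
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
            rows.append(np.array([float(v) for v in parts[2:22]]))
    if not rows:
        raise ValueError("no PSSM rows found in PSI-BLAST output")
    return rows


def read_dssp(text: str) -> dict[ResKey, tuple[str, float]]:
    """Read (secondary-structure class, absolute accessibility) per residue
    from classic DSSP output, keyed by (chain id, residue number)."""
    out: dict[ResKey, tuple[str, float]] = {}
    in_data = False
    for line in text.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_data = True
            continue
        if not in_data or len(line) < 38:
            continue
        if line[13] == "!":  # chain break
            continue
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        chain_id = line[11].strip() or "A"
        ss = line[16].strip()
        acc = float(line[34:38])
        out[(chain_id, resnum)] = (ss, acc)
    if not out:
        raise ValueError("no residue rows found in DSSP output")
    return out


def read_residue_table(text: str, n_values: int) -> dict[ResKey, np.ndarray]:
    """Read a plain TSV of per-residue values: ``chain<TAB>index<TAB>v1..vk``.
    Lines starting with '#' and a header line are ignored."""
    out: dict[ResKey, np.ndarray] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 + n_values:
            continue
        try:
            idx = int(parts[1])
            vals = np.array([float(v) for v in parts[2:2 + n_values]])
        except ValueError:
            continue  # header
        out[(parts[0], idx)] = vals
    return out


def sphere_sampling_asa(chain: Chain,
                        probe: float = PROBE_RADIUS,
                        n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Absolute solvent-accessible surface area (Å²) per residue by sphere
    sampling (Shrake–Rupley): each heavy atom is expanded by the probe
    radius, sampled with an even unit-sphere point set, and points buried in
    any other expanded atom are discarded."""
    from .geometry import _atoms_by_residue, _fibonacci_sphere

    coords, owners = _atoms_by_residue(chain, heavy_only=True)
    elements = []
    for res in chain:
        kept = [a for a in res.atoms if a.is_heavy] or res.atoms
        elements.extend(a.element.upper() for a in kept)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) + probe for e in elements])
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    asa = np.zeros(len(chain))
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * sphere
        neighbor_idx = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbor_idx:
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not exposed.any():
                break
        frac = exposed.mean()
        asa[owners[i]] += frac * 4.0 * np.pi * r * r
    return asa


@dataclass
class ProviderBundle:
    """Resolves per-residue auxiliary values, falling back to documented
    defaults and counting how often each fallback fires."""

    pssm: dict[ResKey, np.ndarray] = field(default_factory=dict)
    conservation: dict[ResKey, float] = field(default_factory=dict)
    disorder: dict[ResKey, np.ndarray] = field(default_factory=dict)
    secondary_structure: dict[ResKey, str] = field(default_factory=dict)
    asa: dict[ResKey, float] = field(default_factory=dict)
    sce: dict[ResKey, np.ndarray] = field(default_factory=dict)
    allow_fallback: bool = True
    fallback_counts: dict[str, int] = field(default_factory=dict)
    _asa_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def _fallback(self, name: str):
        if not self.allow_fallback:
            raise KeyError(
                f"provider {name!r} has no value and fallbacks are disabled")
        self.fallback_counts[name] = self.fallback_counts.get(name, 0) + 1

    def get_pssm(self, key: ResKey, aa: str) -> np.ndarray:
        if key in self.pssm:
            return self.pssm[key]
        self._fallback("pssm")
        return blosum62_row(aa)

    def get_conservation(self, key: ResKey) -> float:
        if key in self.conservation:
            return self.conservation[key]
        self._fallback("conservation")
        return 0.0

    def get_disorder(self, key: ResKey) -> np.ndarray:
        if key in self.disorder:
            return self.disorder[key]
        self._fallback("disorder")
        return np.zeros(N_DISORDER)

    def get_ss(self, key: ResKey) -> str:
        if key in self.secondary_structure:
            return self.secondary_structure[key]
        self._fallback("secondary_structure")
        return " "  # coil

    def get_sce(self, key: ResKey) -> np.ndarray:
        if key in self.sce:
            return self.sce[key]
        self._fallback("sce")
        return np.zeros(N_SCE)

    def get_asa_array(self, chain: Chain) -> np.ndarray:
        """Absolute ASA for every residue of the chain, preferring supplied
        values and filling the rest by sphere sampling."""
        supplied = [self.asa.get(r.key) for r in chain]
        if all(v is not None for v in supplied):
            return np.array(supplied, dtype=float)
        self._fallback("asa")
        cache_key = id(chain)
        if cache_key not in self._asa_cache:
            self._asa_cache[cache_key] = sphere_sampling_asa(chain)
        computed = self._asa_cache[cache_key]
        return np.array([v if v is not None else computed[i]
                         for i, v in enumerate(supplied)], dtype=float)

    @classmethod
    def from_files(cls, *, pssm_texts: dict[str, str] | None = None,
                   dssp_text: str | None = None,
                   conservation_text: str | None = None,
                   disorder_text: str | None = None,
                   sce_text: str | None = None,
                   chains: dict[str, Chain] | None = None,
                   allow_fallback: bool = True) -> "ProviderBundle":
        """Build a bundle from external-tool output texts.

        ``pssm_texts`` maps chain id → PSI-BLAST ASCII PSSM for that chain
        (rows aligned to chain positions).  DSSP rows are matched to residues
        by author residue numbering via ``chains``.
        """
        bundle = cls(allow_fallback=allow_fallback)
        if pssm_texts:
            for cid, text in pssm_texts.items():
                for i, row in enumerate(read_psiblast_pssm(text), start=1):
                    bundle.pssm[(cid, i)] = row
        if dssp_text:
            parsed = read_dssp(dssp_text)
            if chains:
                for cid, chain in chains.items():
                    for res in chain:
                        hit = parsed.get((cid, res.pdb_resseq))
                        if hit is not None:
                            ss, acc = hit
                            bundle.secondary_structure[res.key] = ss
                            bundle.asa[res.key] = acc
            else:
                for (cid, num), (ss, acc) in parsed.items():
                    bundle.secondary_structure[(cid, num)] = ss
                    bundle.asa[(cid, num)] = acc
        if conservation_text:
            for key, vals in read_residue_table(conservation_text, 1).items():
                bundle.conservation[key] = float(vals[0])
        if disorder_text:
            bundle.disorder.update(read_residue_table(disorder_text, N_DISORDER))
        if sce_text:
            bundle.sce.update(read_residue_table(sce_text, N_SCE))
        return bundle
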