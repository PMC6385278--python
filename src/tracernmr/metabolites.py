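"""Packaged metabolite table: reporter CH positions with shifts and couplings.

Serine and creatine C2 carry measured coupling constants (serine
¹J_C1C2 = 53.1 Hz, ¹J_C2C3 = 36.9 Hz, ¹J_C2N2 = 5.9 Hz; creatine
¹J_C1C2 = 54.5 Hz, ¹J_C2N2 = 11.8 Hz); the lactate methyl position is the
δ 1.31/22.9 ppm calibration reference; the alanine H2/C2 position sits at
3.78/53.2 ppm.  Shifts and couplings without a measured source are typical
literature-range values shipped as artifact defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

from .spin_model import SpinSystem

__all__ = ["METABOLITE_TABLE", "get_spin_system", "load_spin_systems", "dump_spin_systems"]

METABOLITE_TABLE: dict[tuple[str, str], SpinSystem] = {
    (s.metabolite_name, s.atom_label): s
    for s in [
        SpinSystem("serine", "C2", shift_h=3.83, shift_c=57.0, multiplicity_x=1,
                   j_cc_left=53.1, j_cc_right=36.9, j_cn=5.9),
        SpinSystem("serine", "C3", shift_h=3.94, shift_c=60.9, multiplicity_x=2,
                   j_cc_left=36.9),
        SpinSystem("creatine", "C2", shift_h=3.93, shift_c=54.7, multiplicity_x=2,
                   j_cc_left=54.5, j_cn=11.8),
        SpinSystem("lactate", "C3", shift_h=1.31, shift_c=22.9, multiplicity_x=3,
                   j_cc_left=37.0),
        SpinSystem("lactate", "C2", shift_h=4.10, shift_c=69.3, multiplicity_x=1,
                   j_cc_left=54.0, j_cc_right=37.0),
        SpinSystem("alanine", "C2", shift_h=3.78, shift_c=53.2, multiplicity_x=1,
                   j_cc_left=54.0, j_cc_right=35.0, j_cn=6.0),
        SpinSystem("alanine", "C3", shift_h=1.48, shift_c=16.8, multiplicity_x=3,
                   j_cc_left=35.0),
        SpinSystem("glutamate", "C4", shift_h=2.34, shift_c=34.2, multiplicity_x=2,
                   j_cc_left=34.0, j_cc_right=51.0),
        SpinSystem("aspartate", "C2", shift_h=3.89, shift_c=52.2, multiplicity_x=1,
                   j_cc_left=54.0, j_cc_right=36.0, j_cn=6.0),
        SpinSystem("malate", "C2", shift_h=4.30, shift_c=71.2, multiplicity_x=1,
                   j_cc_left=53.5, j_cc_right=36.0),
    ]
}


def get_spin_system(metabolite: str, atom: str) -> SpinSystem:
    try:
        return METABOLITE_TABLE[(metabolite, atom)]
    except KeyError:
        raise KeyError(f"no packaged spin system for {metabolite} {atom}") from None


def dump_spin_systems(path: str | Path, systems: list[SpinSystem] | None = None) -> None:
    """Write spin systems to a JSON file (list of records)."""
    systems = list(METABOLITE_TABLE.values()) if systems is None else systems
    Path(path).write_text(json.dumps([s.to_dict() for s in systems], indent=1))


def load_spin_systems(path: str | Path) -> list[SpinSystem]:
    """Read spin systems from a JSON file written by :func:`dump_spin_systems`."""
    records = json.loads(Path(path).read_text())
    if isinstance(records, dict):
        records = [records]
    return [SpinSystem.from_dict(r) for r in records]
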