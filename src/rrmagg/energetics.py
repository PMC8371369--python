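"""MM-PBSA energy bookkeeping and per-residue decomposition filtering.

The package computes no Poisson–Boltzmann or surface-area energies; it
combines precomputed components with the standard algebra

    ΔG_np = ΔE_vdw + ΔG_np/solv
    ΔG_pb = ΔE_ele + ΔG_pb/solv
    ΔH_binding = ΔG_np + ΔG_pb + ΔE_int
    ΔG_binding = ΔH_binding − TΔS

(all in kcal/mol; TΔS is stored as the printed product, never split), and
validates published tables against that algebra.  Printed tables are rounded
to 2 decimals, so the consistency checker allows the accumulated rounding
slack of the inputs (±0.005 each) instead of demanding bitwise identity; a
genuinely inconsistent cell is flagged, never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EnergyComponents",
    "DerivedEnergies",
    "derive_energies",
    "complex_minus_parts",
    "crucial_residues",
    "read_components_table",
    "consistency_report",
    "load_reference_components",
]

COMPONENT_FIELDS = ("dE_ele", "dE_vdw", "dE_int", "dG_np_solv", "dG_pb_solv", "TdS")
DERIVED_FIELDS = ("dG_np", "dG_pb", "dH_binding", "dG_binding")

#: printed inputs feeding each derived quantity (for rounding-slack bounds)
_N_INPUTS = {"dG_np": 2, "dG_pb": 2, "dH_binding": 5, "dG_binding": 6}
_ROUND = 0.005  # half-ulp of a 2-decimal print


@dataclass(frozen=True)
class EnergyComponents:
    """MM-PBSA components in kcal/mol; TdS is the product T·ΔS as printed."""

    dE_ele: float
    dE_vdw: float
    dE_int: float
    dG_np_solv: float
    dG_pb_solv: float
    TdS: float

    def __post_init__(self):
        for f in COMPONENT_FIELDS:
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"non-finite component {f}")


@dataclass(frozen=True)
class DerivedEnergies:
    dG_np: float
    dG_pb: float
    dH_binding: float
    dG_binding: float


def derive_energies(components: EnergyComponents) -> DerivedEnergies:
    """Combine components into the derived binding-energy terms."""
    dG_np = components.dE_vdw + components.dG_np_solv
    dG_pb = components.dE_ele + components.dG_pb_solv
    dH = dG_np + dG_pb + components.dE_int
    dG = dH - components.TdS
    return DerivedEnergies(dG_np, dG_pb, dH, dG)


def complex_minus_parts(g_complex: float, g_ligand: float, g_receptor: float) -> float:
    """ΔG_binding = G_complex − (G_ligand + G_receptor)."""
    for v in (g_complex, g_ligand, g_receptor):
        if not np.isfinite(v):
            raise ValueError("non-finite free energy")
    return float(g_complex - (g_ligand + g_receptor))


def crucial_residues(decomposition: dict | pd.Series,
                     threshold: float = -2.0) -> list:
    """Residues whose decomposition energy is strictly below ``threshold``.

    Matches the convention of calling a residue crucial when it contributes
    more than 2 kcal/mol of binding energy, i.e. a per-residue value below
    −2 kcal/mol.  Sorted ascending by value (strongest contributors first).
    """
    if len(decomposition) == 0:
        raise ValueError("empty residue decomposition")
    items = (decomposition.items() if hasattr(decomposition, "items")
             else list(decomposition))
    hits = [(k, float(v)) for k, v in items if float(v) < threshold]
    hits.sort(key=lambda kv: kv[1])
    return [k for k, _ in hits]


def read_components_table(source) -> pd.DataFrame:
    """Read a tabular file of components (one row per model).

    Requires a ``model`` column plus the six component columns; optional
    printed derived columns are kept for consistency checking.  Malformed
    numbers raise with a cell reference.
    """
    df = pd.read_csv(source, sep="\t")
    if df.empty:
        raise ValueError("empty components table")
    if "model" not in df.columns:
        raise ValueError("components table requires a 'model' column")
    missing = [c for c in COMPONENT_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"components table missing columns: {missing}")
    for col in list(COMPONENT_FIELDS) + [c for c in DERIVED_FIELDS if c in df.columns]:
        for row_i, raw in enumerate(df[col]):
            try:
                float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed number in column {col!r}, row {row_i + 1} "
                    f"(model {df['model'].iloc[row_i]!r}): {raw!r}") from None
        df[col] = df[col].astype(float)
    return df.set_index("model")


def _tolerance(quantity: str) -> float:
    return _ROUND * (_N_INPUTS[quantity] + 1)


def consistency_report(table: pd.DataFrame) -> pd.DataFrame:
    """Cross-check printed derived cells against the component algebra.

    For each model the report recomputes every derived quantity from the raw
    components and, additionally, checks the printed chain
    ΔG_binding = ΔH_binding(printed) − TΔS.  A cell is consistent when it
    matches within the accumulated print-rounding slack; discrepancies are
    reported with their magnitude, never altered.
    """
    rows = []
    for model, r in table.iterrows():
        comp = EnergyComponents(**{f: float(r[f]) for f in COMPONENT_FIELDS})
        derived = derive_energies(comp)
        for q in DERIVED_FIELDS:
            if q not in table.columns:
                continue
            printed = float(r[q])
            computed = getattr(derived, q)
            delta = printed - computed
            rows.append({
                "model": model, "quantity": q, "printed": printed,
                "computed": round(computed, 6), "delta": round(delta, 6),
                "consistent": bool(abs(delta) <= _tolerance(q)),
                "check": "components",
            })
        if "dG_binding" in table.columns and "dH_binding" in table.columns:
            chain = float(r["dH_binding"]) - comp.TdS
            delta = float(r["dG_binding"]) - chain
            rows.append({
                "model": model, "quantity": "dG_binding", "printed": float(r["dG_binding"]),
                "computed": round(chain, 6), "delta": round(delta, 6),
                "consistent": bool(abs(delta) <= 3 * _ROUND),
                "check": "printed_chain",
            })
    return pd.DataFrame(rows)


def load_reference_components() -> pd.DataFrame:
    """Published MM-PBSA components for the five TDP-43 RRM12 dimer models.

    Shipped as package data; the printed derived rows are included verbatim
    so the consistency checker can exercise them.
    """
    with resources.files("rrmagg.data").joinpath(
            "dimer_energy_components.tsv").open() as fh:
        return read_components_table(fh)


def load_reference_occupancies() -> pd.DataFrame:
    """Published interface interaction occupancies for the five dimer models."""
    with resources.files("rrmagg.data").joinpath(
            "dimer_interface_occupancies.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["occupancy"] = df["occupancy"].astype(float)
    return df
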