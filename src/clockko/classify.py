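"""Partition double-knockout DEGs into redundancy vs isoform-dominance classes.

A gene that is differentially expressed in the double knockout (NDKO) is
assigned, per direction, to exactly one of:

* ``ndko_exclusive`` — DEG in neither single mutant: evidence of redundant
  or compensatory regulation by the two isoforms.
* ``alpha_dominant`` — also a DEG (same direction) in N1KO while N2KO moves
  less than the secondary fold bound (default 1.3): NR1D1 (REV-ERBalpha)
  drives the change.
* ``beta_dominant`` — the mirror image with N2KO significant and N1KO flat.
* ``shared`` — everything else (e.g. significant in both single mutants, or
  in one single mutant with the other exceeding the secondary bound).
* ``ambiguous`` — qualifies as both alpha- and beta-dominant (possible only
  under conflicting threshold settings).

For the down direction the secondary bound is the reciprocal: the other
single mutant must show fc > 1/1.3, i.e. less than a 1.3-fold decrease.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["classify", "venn_summary", "exclusive_pct"]

_CLASS_ORDER = ("ndko_exclusive", "alpha_dominant", "beta_dominant", "shared", "ambiguous")


def _wide(contrasts: pd.DataFrame) -> pd.DataFrame:
    need = {"gene", "genotype", "fc", "p", "deg_up", "deg_down"}
    missing = need - set(contrasts.columns)
    if missing:
        raise ValueError(f"contrast table missing columns: {sorted(missing)}")
    counts = contrasts.groupby("gene")["genotype"].nunique()
    incomplete = counts.index[counts < 3]
    if len(incomplete):
        raise ValueError(
            "genes missing contrasts for some genotype: "
            f"{list(incomplete[:5])}{'...' if len(incomplete) > 5 else ''}"
        )
    wide = contrasts.pivot(
        index="gene", columns="genotype", values=["fc", "p", "deg_up", "deg_down"]
    )
    wide.columns = [f"{v}_{g}" for v, g in wide.columns]
    for col in wide.columns:  # pivot of mixed values yields object dtype
        dtype = bool if col.startswith("deg_") else float
        wide[col] = wide[col].astype(dtype)
    return wide


def classify(contrasts: pd.DataFrame, fc_secondary: float = 1.3) -> pd.DataFrame:
    """Classify every NDKO DEG; one row per gene-direction.

    ``contrasts`` is the long-form table from :func:`clockko.diffexpr.contrast_all`
    covering all three mutant genotypes. Returns columns gene, direction,
    label, and the supporting fc/p values per genotype.
    """
    wide = _wide(contrasts)
    rows = []
    for direction in ("up", "down"):
        flag = f"deg_{direction}"
        nd = wide[wide[f"{flag}_NDKO"]]
        if direction == "up":
            n2_flat = nd["fc_N2KO"] < fc_secondary
            n1_flat = nd["fc_N1KO"] < fc_secondary
        else:
            n2_flat = nd["fc_N2KO"] > 1.0 / fc_secondary
            n1_flat = nd["fc_N1KO"] > 1.0 / fc_secondary
        alpha = nd[f"{flag}_N1KO"].to_numpy() & n2_flat.to_numpy()
        beta = nd[f"{flag}_N2KO"].to_numpy() & n1_flat.to_numpy()
        neither = ~nd[f"{flag}_N1KO"].to_numpy() & ~nd[f"{flag}_N2KO"].to_numpy()
        label = np.select(
            [alpha & beta, alpha, beta, neither],
            ["ambiguous", "alpha_dominant", "beta_dominant", "ndko_exclusive"],
            default="shared",
        )
        part = pd.DataFrame(
            {
                "gene": nd.index,
                "direction": direction,
                "label": label,
                "fc_N1KO": nd["fc_N1KO"].to_numpy(),
                "p_N1KO": nd["p_N1KO"].to_numpy(),
                "fc_N2KO": nd["fc_N2KO"].to_numpy(),
                "p_N2KO": nd["p_N2KO"].to_numpy(),
                "fc_NDKO": nd["fc_NDKO"].to_numpy(),
                "p_NDKO": nd["p_NDKO"].to_numpy(),
            }
        )
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def exclusive_pct(n_exclusive: int, n_total: int) -> float:
    """NDKO-exclusive DEGs as a percentage of all NDKO DEGs, 2 decimals.

    Undefined (NaN) when the NDKO DEG set is empty.
    """
    if n_total == 0:
        return float("nan")
    return round(100.0 * n_exclusive / n_total, 2)


def venn_summary(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Three-way DEG set intersections per direction.

    For each direction the membership sets are the per-genotype DEG sets;
    all seven intersection cells are reported together with the
    NDKO-exclusive count and its percentage of the NDKO set (NaN when that
    set is empty). Indexed by direction.
    """
    wide = _wide(contrasts)
    out = {}
    for direction in ("up", "down"):
        flag = f"deg_{direction}"
        a = set(wide.index[wide[f"{flag}_N1KO"]])
        b = set(wide.index[wide[f"{flag}_N2KO"]])
        d = set(wide.index[wide[f"{flag}_NDKO"]])
        only_nd = d - a - b
        out[direction] = {
            "n_N1KO": len(a),
            "n_N2KO": len(b),
            "n_NDKO": len(d),
            "only_N1KO": len(a - b - d),
            "only_N2KO": len(b - a - d),
            "only_NDKO": len(only_nd),
            "N1KO_N2KO_only": len((a & b) - d),
            "N1KO_NDKO_only": len((a & d) - b),
            "N2KO_NDKO_only": len((b & d) - a),
            "all_three": len(a & b & d),
            "ndko_exclusive_pct": exclusive_pct(len(only_nd), len(d)),
        }
    df = pd.DataFrame(out).T
    df.index.name = "direction"
    int_cols = [c for c in df.columns if c != "ndko_exclusive_pct"]
    df[int_cols] = df[int_cols].astype(int)
    return df
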