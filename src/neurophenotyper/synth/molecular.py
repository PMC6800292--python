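"""Synthetic qRT-PCR Ct tables and expression matrices with planted effects."""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_ct_table(
    group_sizes: dict[str, int],
    fold_changes: dict[str, dict[str, float]],
    target_genes: list[str],
    reference_gene: str = "GAPDH",
    base_ct_reference: float = 18.0,
    base_delta_ct: float = 6.0,
    ct_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy Ct table (sample, group, gene, ct) with known relative expression.

    ``fold_changes[group][gene]`` is the true expression of ``gene`` in
    ``group`` relative to the calibrator group (fold 1 = calibrator level);
    one PCR cycle corresponds to a factor of two, so a fold change f shifts
    ΔCt by -log2(f). Replicate noise of SD ``ct_sd`` cycles is added to
    every well.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in group_sizes.items():
        for rep in range(n):
            sample = f"{group}_{rep}"
            ct_ref = base_ct_reference + rng.normal(0, ct_sd)
            rows.append({"sample": sample, "group": group, "gene": reference_gene, "ct": ct_ref})
            for gene in target_genes:
                fold = fold_changes.get(group, {}).get(gene, 1.0)
                dct = base_delta_ct - np.log2(fold)
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "ct": ct_ref + dct + rng.normal(0, ct_sd),
                    }
                )
    return pd.DataFrame(rows)


def generate_expression_matrix(
    n_genes: int = 1000,
    groups: dict[str, int] = None,
    planted: dict[str, dict[str, float]] = None,
    base_level: float = 100.0,
    cv: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Linear-scale expression matrix (genes x samples) with planted DEGs.

    ``planted[contrast_group][gene] = fold`` plants that fold change (vs the
    first group) on the named gene. Returns (matrix, sample->group mapping,
    planted gene lists per group).
    """
    groups = groups or {"control": 3, "case": 3}
    planted = planted or {}
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_cols, group_of = [], {}
    for g, n in groups.items():
        for r in range(n):
            s = f"{g}_{r}"
            sample_cols.append(s)
            group_of[s] = g

    mat = pd.DataFrame(index=gene_ids, columns=sample_cols, dtype=float)
    for s in sample_cols:
        g = group_of[s]
        level = np.full(n_genes, base_level)
        for gene, fold in planted.get(g, {}).items():
            level[gene_ids.index(gene)] *= fold
        mat[s] = level * rng.lognormal(0.0, cv, size=n_genes)
    planted_lists = {g: sorted(d) for g, d in planted.items()}
    return mat, pd.Series(group_of), planted_lists
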