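"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from redoxreg.models import GeneModel, GenomeAnnotation

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


# ----------------------------------------------------------- oracles


def bh_bruteforce(pvalues: list[float]) -> list[float]:
    """Step-up BH computed naively from the definition:
    adj_(i) = min_{j >= i} p_(j) * m / j on the sorted p values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj_sorted = [
        min(min(pvalues[order[j]] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)
    ]
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out


def tc_bruteforce(cand_rows: list[dict], max_gap: int = 250) -> tuple[set, set]:
    """Exhaustive TC enumeration: all maximal contiguous same-strand runs
    of candidates with every internal gap < max_gap and one direction.

    ``cand_rows`` carry gene_id/contig/strand/start/end/direction.
    Returns (set of member tuples for runs of >= 2, set of isolated ids).
    """

    def valid(run: list[dict]) -> bool:
        for a, b in zip(run, run[1:]):
            if b["start"] - a["end"] - 1 >= max_gap or a["direction"] != b["direction"]:
                return False
        return True

    tcs, isolated = set(), set()
    groups: dict[tuple, list[dict]] = {}
    for r in cand_rows:
        groups.setdefault((r["contig"], r["strand"]), []).append(r)
    for rows in groups.values():
        rows = sorted(rows, key=lambda r: r["start"])
        n = len(rows)
        for i in range(n):
            for j in range(i, n):
                run = rows[i : j + 1]
                if not valid(run):
                    continue
                left_ok = i > 0 and valid(rows[i - 1 : j + 1])
                right_ok = j < n - 1 and valid(rows[i : j + 2])
                if left_ok or right_ok:
                    continue  # extendable -> not maximal
                if len(run) >= 2:
                    tcs.add(tuple(r["gene_id"] for r in run))
                else:
                    isolated.add(run[0]["gene_id"])
    return tcs, isolated


def random_candidate_layout(rng: np.random.Generator, n_max: int = 12):
    """A random candidate layout: sequentially placed genes (so no
    overlap), random strands and directions, gaps straddling the 250 bp
    threshold. Returns (annotation, candidates DataFrame)."""
    n = int(rng.integers(1, n_max + 1))
    genes, rows = [], []
    cursor = 1
    for i in range(n):
        length = int(rng.integers(100, 800))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i + 1}"
        genes.append(GeneModel(gid, "c1", cursor, cursor + length - 1, strand))
        direction = "down" if rng.random() < 0.5 else "up"
        fc = (-1 if direction == "down" else 1) * float(rng.uniform(2, 50))
        rows.append(
            {
                "gene_id": gid,
                "contig": "c1",
                "strand": strand,
                "start": cursor,
                "end": cursor + length - 1,
                "direction": direction,
                "fc": fc,
            }
        )
        cursor += length + int(rng.integers(0, 500))
    annotation = GenomeAnnotation(genes)
    candidates = pd.DataFrame(rows).set_index("gene_id")[["fc", "direction"]]
    return annotation, candidates, rows


# ----------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def recovery_result():
    """The planted-recovery benchmark, run once per session."""
    from redoxreg.benchmark import run_recovery

    return run_recovery(seed=1)


def make_de_frame(records: dict[str, dict]) -> pd.DataFrame:
    """Minimal DE frame from {gene_id: {fc, pvalue, padj, ...}}."""
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "gene_id"
    for col, default in (("base_mean", 100.0), ("pvalue", 0.001), ("padj", 0.001), ("tested", True)):
        if col not in df:
            df[col] = default
    if "log2fc" not in df:
        from redoxreg.models import lfc_from_fc

        df["log2fc"] = [lfc_from_fc(v) for v in df["fc"]]
    return df
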