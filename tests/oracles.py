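"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exact integer combinatorics and
nested loops — and shares no code path with the package internals it checks.
"""

from math import comb

import numpy as np


def fisher_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(one-tailed, two-tailed) Fisher p by full enumeration over all tables
    with the observed margins, using exact integer weights.

    One-tailed: P(top-left >= a). Two-tailed: sum of point probabilities no
    larger than the observed table's (minimum-likelihood convention). Integer
    weights make tie handling exact.
    """
    r, s = a + b, c + d
    n, k = r + s, a + c
    if n == 0:
        return 1.0, 1.0
    lo, hi = max(0, k - s), min(r, k)
    weights = {x: comb(r, x) * comb(s, k - x) for x in range(lo, hi + 1)}
    total = comb(n, k)
    observed = weights[a]
    one = sum(w for x, w in weights.items() if x >= a) / total
    two = sum(w for w in weights.values() if w <= observed) / total
    return one, two


def collapse_oracle(dataset) -> dict[str, dict[str, float]]:
    """Per-gene burden/carrier tally by an exhaustive loop over every
    (sample, variant) pair of the dataset."""
    gene_of = {v.key.id: v.gene for v in dataset.variants}
    out: dict[str, dict[str, float]] = {}
    for sample in dataset.genotypes.index:
        group = dataset.phenotypes[sample]
        for vid in dataset.genotypes.columns:
            dosage = dataset.genotypes.at[sample, vid]
            if not np.isfinite(dosage) or dosage <= 0:
                continue
            gene = gene_of[vid]
            cell = out.setdefault(
                gene,
                {"case_burden": 0, "control_burden": 0,
                 "case_carriers": set(), "control_carriers": set()},
            )
            cell[f"{group}_burden"] += int(dosage)
            cell[f"{group}_carriers"].add(sample)
    return {
        gene: {
            "case_burden": cell["case_burden"],
            "control_burden": cell["control_burden"],
            "case_carriers": len(cell["case_carriers"]),
            "control_carriers": len(cell["control_carriers"]),
        }
        for gene, cell in out.items()
    }


def _required(value: float, wanted: int) -> bool:
    return np.isfinite(value) and int(value) == wanted


def segregation_oracle(family) -> dict[str, set]:
    """Re-derive all three inheritance-model hit sets by direct predicate
    evaluation over every variant (and every variant pair per gene)."""
    sibs = [m.individual_id for m in family.pedigree.affected]
    parents = sorted(
        {m.father_id for m in family.pedigree.affected}
        | {m.mother_id for m in family.pedigree.affected}
    )
    p1, p2 = parents
    dos = family.dosages
    gene_of = {v.key.id: v.gene for v in family.variants}

    de_novo, hom_rec, comp_het = set(), set(), set()
    cols = list(dos.columns)
    for vid in cols:
        if all(_required(dos.at[s, vid], 1) for s in sibs) and all(
            _required(dos.at[p, vid], 0) for p in (p1, p2)
        ):
            de_novo.add(vid)
        if all(_required(dos.at[s, vid], 2) for s in sibs) and all(
            _required(dos.at[p, vid], 1) for p in (p1, p2)
        ):
            hom_rec.add(vid)
    for i, v1 in enumerate(cols):
        for v2 in cols[i + 1:]:
            if gene_of[v1] != gene_of[v2]:
                continue
            if not all(
                _required(dos.at[s, v1], 1) and _required(dos.at[s, v2], 1) for s in sibs
            ):
                continue
            trans_a = (
                _required(dos.at[p1, v1], 1) and _required(dos.at[p1, v2], 0)
                and _required(dos.at[p2, v2], 1) and _required(dos.at[p2, v1], 0)
            )
            trans_b = (
                _required(dos.at[p2, v1], 1) and _required(dos.at[p2, v2], 0)
                and _required(dos.at[p1, v2], 1) and _required(dos.at[p1, v1], 0)
            )
            if trans_a or trans_b:
                comp_het.add(frozenset((v1, v2)))
    return {"de_novo": de_novo, "hom_recessive": hom_rec, "compound_het": comp_het}


def tally_oracle(dataset, vid: str, strata: tuple[str, ...]) -> dict:
    """Exhaustive genotype-class tally for one variant id."""
    counts: dict[tuple[str, int], int] = {}
    n = {s: 0 for s in strata}
    for sample in dataset.genotypes.index:
        stratum = dataset.severity[sample]
        value = dataset.genotypes.at[sample, vid]
        if stratum not in n or not np.isfinite(value):
            continue
        counts[(stratum, int(value))] = counts.get((stratum, int(value)), 0) + 1
        n[stratum] += 1
    return {"counts": counts, "n": n}
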