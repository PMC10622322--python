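"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's enumeration code paths: digestion
is checked by filtering *all* substrings for cleavage-consistent
boundaries, classification by direct enumeration over (peptide, record)
pairs, and q-values by evaluating the FDR at every distinct score.
"""

from __future__ import annotations

NONSTANDARD = set("XBZUJO")


def site_flags(sequence: str, proline_rule: bool = True) -> list[bool]:
    flags = [False] * len(sequence)
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            flags[i] = True
    return flags


def brute_force_digest(
    sequence: str,
    max_missed: int = 2,
    length_range: tuple[int, int] = (8, 40),
    proline_rule: bool = True,
) -> set[tuple[str, int, int, int]]:
    """All substrings whose boundaries are cleavage-consistent.

    Returns tuples (peptide, start, end, internal site count).
    """
    n = len(sequence)
    flags = site_flags(sequence, proline_rule)
    cum = [0]
    for f in flags:
        cum.append(cum[-1] + (1 if f else 0))
    lo, hi = length_range
    out: set[tuple[str, int, int, int]] = set()
    for start in range(n):
        if start != 0 and not flags[start - 1]:
            continue
        for end in range(start + lo, min(start + hi, n) + 1):
            if end != n and not flags[end - 1]:
                continue
            internal = cum[end - 1] - cum[start]
            if internal > max_missed:
                continue
            pep = sequence[start:end]
            if NONSTANDARD & set(pep):
                continue
            out.add((pep, start, end, internal))
    return out


def brute_force_classify(records) -> dict[str, dict]:
    """Enumerate every (peptide, record) pair and classify directly.

    Returns per peptide: min substitution burden, gene set, record set.
    Contaminant records count as their own gene.
    """
    table: dict[str, dict] = {}
    for rec in records:
        for pep, start, end, _mc in brute_force_digest(rec.sequence):
            if any(start < j < end for j in rec.stop_junctions):
                continue
            burden = sum(
                1 for s in rec.substitutions if start <= s.position - 1 < end
            )
            gene = rec.gene_id if rec.gene_id else f"contaminant:{rec.accession}"
            entry = table.setdefault(
                pep, {"min_burden": burden, "genes": set(), "records": set()}
            )
            entry["min_burden"] = min(entry["min_burden"], burden)
            entry["genes"].add(gene)
            entry["records"].add(rec.accession)
    for entry in table.values():
        if len(entry["genes"]) > 1:
            entry["specificity"] = "nonspecific"
        elif len(entry["records"]) > 1:
            entry["specificity"] = "protein_specific"
        else:
            entry["specificity"] = "proteoform_specific"
        entry["variant"] = (
            "canonical"
            if entry["min_burden"] == 0
            else "single_variant"
            if entry["min_burden"] == 1
            else "multivariant"
        )
    return table


def brute_force_qvalues(scores, labels) -> list[float]:
    """q-value = min over thresholds <= own score of FDR at that threshold."""
    thresholds = sorted(set(scores))
    fdr_at: dict[float, float] = {}
    for t in thresholds:
        d = sum(1 for s, l in zip(scores, labels) if s >= t and l == "decoy")
        n = sum(1 for s, l in zip(scores, labels) if s >= t and l == "target")
        fdr_at[t] = (d / n) if n else float("inf")
    out = []
    for s in scores:
        eligible = [fdr_at[t] for t in thresholds if t <= s]
        out.append(min(1.0, min(eligible)))
    return out
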