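"""Cohort-level summary arithmetic for the reported tables.

Small, exact computations over count tables: the interaction-type
preference (re-exported from interface_extraction), the fraction of
domains that are multi-interface, the share of multi-interface proteins
in a subset of structural classes, and the mean number of interfaces per
multi-interface protein.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .interface_extraction import compute_preference  # noqa: F401  (re-export)


def multi_domain_fraction(n_multi_domains: int, n_total_domains: int) -> float:
    """Percentage of annotated domains that are multi-interface."""
    if n_total_domains <= 0:
        raise ValueError("total domain count must be positive")
    return 100.0 * n_multi_domains / n_total_domains


def class_share(class_counts: Mapping[str, int], classes: Sequence[str],
                total: int) -> float:
    """Percentage of proteins falling in the given structural classes."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * sum(class_counts[c] for c in classes) / total


def mean_interfaces_per_protein(total_interfaces: int, n_proteins: int) -> float:
    """Average interface count over multi-interface proteins."""
    if n_proteins <= 0:
        raise ValueError("protein count must be positive")
    return total_interfaces / n_proteins
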