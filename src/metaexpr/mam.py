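"""Molecular alteration map assembly and Fisher-exact over-representation.

The map assigns each gene from the union of per-comparison top-k sets to
named regions defined by boolean membership patterns over the comparisons
("in top-k of A but not B"), recording per-comparison direction from the
sign of the combined Z. Genes matching no configured region land in the
``unassigned`` bin so the partition always closes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from metaexpr.core_io import ValidationError
from metaexpr.diffexp import bh_adjust
from metaexpr.integrate import IntegrationResult

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RegionSpec:
    """One region: comparisons a member gene must be in, and must not be in."""

    name: str
    required_in: frozenset[str]
    required_out: frozenset[str]

    def matches(self, membership: frozenset[str]) -> bool:
        return self.required_in <= membership and not (self.required_out & membership)


def load_region_spec(path: str | Path) -> list[RegionSpec]:
    """Read a region spec from YAML: list of {name, required_in, required_out}."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    specs = [
        RegionSpec(
            name=str(entry["name"]),
            required_in=frozenset(entry.get("required_in", [])),
            required_out=frozenset(entry.get("required_out", [])),
        )
        for entry in raw
    ]
    _check_region_spec(specs)
    return specs


def _check_region_spec(specs: list[RegionSpec]) -> None:
    seen: dict[tuple[frozenset, frozenset], str] = {}
    for s in specs:
        key = (s.required_in, s.required_out)
        if key in seen:
            raise ValidationError(
                f"regions {seen[key]!r} and {s.name!r} share the same pattern"
            )
        if s.required_in & s.required_out:
            raise ValidationError(f"region {s.name!r}: in/out sets overlap")
        seen[key] = s.name
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate region names")


def default_region_spec(comparisons: list[str]) -> list[RegionSpec]:
    """Shipped default: one exclusive region per comparison plus pairwise
    intersection regions for adjacent stage transitions.

    This encoding is a reconstruction of a natural stage-hallmark reading,
    not a canonical table; supply a custom spec to override.
    """
    others = lambda c: frozenset(comparisons) - {c}
    specs = [
        RegionSpec(f"{c}_only", frozenset([c]), others(c)) for c in comparisons
    ]
    for a, b in zip(comparisons, comparisons[1:]):
        specs.append(
            RegionSpec(
                f"{a}_and_{b}",
                frozenset([a, b]),
                frozenset(comparisons) - {a, b},
            )
        )
    _check_region_spec(specs)
    return specs


@dataclass
class MolecularAlterationMap:
    """Region -> signed gene-set assignment across stage comparisons.

    ``assignments`` has one row per (gene, region) pair with per-comparison
    direction columns (``up``/``down``/``""`` when the gene is not in that
    comparison's top-k).
    """

    regions: list[RegionSpec]
    comparisons: list[str]
    k: int
    assignments: pd.DataFrame

    def region_genes(self, region: str) -> list[str]:
        sub = self.assignments[self.assignments["region"] == region]
        return sub["gene"].tolist()

    def region_counts(self) -> pd.DataFrame:
        """Per-region member counts with up/down tallies per comparison."""
        rows = []
        for region in [s.name for s in self.regions] + [UNASSIGNED]:
            sub = self.assignments[self.assignments["region"] == region]
            row = {"region": region, "n_genes": len(sub)}
            for c in self.comparisons:
                row[f"up_{c}"] = int((sub[f"dir_{c}"] == "up").sum())
                row[f"down_{c}"] = int((sub[f"dir_{c}"] == "down").sum())
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)


def assemble_mam(
    results: dict[str, IntegrationResult],
    k: int,
    region_spec: list[RegionSpec] | None = None,
) -> MolecularAlterationMap:
    """Assign top-k genes of each comparison to every matching region.

    Membership pattern per gene = the set of comparisons in whose top-k it
    appears; direction per member comparison = sign of the combined Z.
    Deterministic and invariant to comparison input order.
    """
    comparisons = sorted(results)
    if region_spec is None:
        region_spec = default_region_spec(comparisons)
    _check_region_spec(region_spec)
    unknown = set().union(
        *(s.required_in | s.required_out for s in region_spec)
    ) - set(comparisons)
    if unknown:
        raise ValidationError(f"region spec references unknown comparisons: {sorted(unknown)}")

    top: dict[str, set[str]] = {}
    direction: dict[str, dict[str, str]] = {}
    for c in comparisons:
        res = results[c]
        if k > len(res.table):
            raise ValidationError(
                f"k={k} exceeds {len(res.table)} genes in comparison {c!r}"
            )
        genes = res.top_genes(k) if k > 0 else []
        top[c] = set(genes)
        z = res.table["z_combined"]
        direction[c] = {
            g: ("up" if z.loc[g] >= 0 else "down") for g in genes
        }

    union = sorted(set().union(*top.values())) if top else []
    rows = []
    for gene in union:
        membership = frozenset(c for c in comparisons if gene in top[c])
        matched = [s.name for s in region_spec if s.matches(membership)]
        if not matched:
            matched = [UNASSIGNED]
        for region in matched:
            row = {"gene": gene, "region": region}
            for c in comparisons:
                row[f"dir_{c}"] = direction[c].get(gene, "")
            rows.append(row)
    columns = ["gene", "region"] + [f"dir_{c}" for c in comparisons]
    assignments = pd.DataFrame(rows, columns=columns)
    return MolecularAlterationMap(
        regions=list(region_spec), comparisons=comparisons, k=k, assignments=assignments
    )


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read annotation gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3 and parts[0]:
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def fisher_ora(
    genes: set[str],
    annotation_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per annotation set.

    Annotation sets are intersected with the universe first. Returns a frame
    sorted by p with columns set, overlap, set_size, odds_ratio, p, q. The
    odds ratio is the sample (a*d)/(b*c), +inf when b*c == 0.
    """
    if not genes or not universe:
        raise ValidationError("empty gene set or universe")
    if not set(genes) <= set(universe):
        raise ValidationError("query genes must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(genes)
    rows = []
    for name, members in annotation_sets.items():
        members = members & universe
        a = len(genes & members)  # query ∧ annotation
        b = n_query - a
        c = len(members) - a
        d = n_universe - n_query - c
        p = float(stats.hypergeom.sf(a - 1, n_universe, len(members), n_query))
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append(
            {
                "set": name,
                "overlap": a,
                "set_size": len(members),
                "odds_ratio": odds,
                "p": min(max(p, np.finfo(float).tiny), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return out
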