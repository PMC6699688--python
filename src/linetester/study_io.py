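"""Data model and I/O for line x tester trials and codominant SSR panels.

Every downstream stage (ANOVA, combining ability, heterosis, marker
diversity) consumes only the types defined here: a :class:`TrialDesign`
describing the balanced l x t x r mating/field layout, plot-level
:class:`PlotRecord` observations, per-entry :class:`EntryMeans`, and a
diploid :class:`GenotypeMatrix` with explicit missing calls.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "TrialDesign",
    "PlotRecord",
    "EntryMeans",
    "GenotypeMatrix",
    "read_phenotypes",
    "write_phenotypes",
    "entry_means",
    "read_genotypes",
    "write_genotypes",
    "read_fixture_table",
    "check_balance",
]

ROLES = ("line_parent", "tester_parent", "cross", "check")


@dataclass(frozen=True)
class TrialDesign:
    """Balanced line x tester mating design: l female lines crossed to t
    male testers, grown in r complete replicates, optionally with check
    entries alongside."""

    line_ids: tuple[str, ...]
    tester_ids: tuple[str, ...]
    n_reps: int
    check_ids: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        object.__setattr__(self, "tester_ids", tuple(self.tester_ids))
        object.__setattr__(self, "check_ids", tuple(self.check_ids))
        if len(self.line_ids) < 2:
            raise ValueError("need at least 2 lines")
        if len(self.tester_ids) < 2:
            raise ValueError("need at least 2 testers")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        all_ids = self.line_ids + self.tester_ids + self.check_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("entry identifiers must be unique across lines, testers and checks")

    @property
    def l(self) -> int:
        return len(self.line_ids)

    @property
    def t(self) -> int:
        return len(self.tester_ids)

    @property
    def r(self) -> int:
        return self.n_reps

    def cross_ids(self) -> list[tuple[str, str]]:
        """All l*t (line, tester) pairs in design order."""
        return [(li, tj) for li in self.line_ids for tj in self.tester_ids]

    @staticmethod
    def cross_label(line_id: str, tester_id: str) -> str:
        return f"{line_id} x {tester_id}"


@dataclass
class PlotRecord:
    """One plot observation: an entry grown in one replicate, with its
    trait measurements (plot means over sampled plants)."""

    entry: str
    role: str
    rep: int
    traits: dict[str, float]
    cross_parents: tuple[str, str] | None = None
    block: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "cross" and self.cross_parents is None:
            raise ValueError(f"cross entry {self.entry!r} lacks parent ids")
        if self.role != "cross" and self.cross_parents is not None:
            raise ValueError(f"non-cross entry {self.entry!r} carries parent ids")


@dataclass
class EntryMeans:
    """Per-entry arithmetic means over replicates for a single trait."""

    trait: str
    values: dict[str, float]
    counts: dict[str, int]

    def __getitem__(self, entry: str) -> float:
        return self.values[entry]

    def subset(self, entries: Iterable[str]) -> "EntryMeans":
        entries = list(entries)
        return EntryMeans(
            self.trait,
            {e: self.values[e] for e in entries},
            {e: self.counts[e] for e in entries},
        )


class GenotypeMatrix:
    """Diploid codominant genotype calls for individuals x loci.

    Calls are unordered pairs of opaque allele labels; missing calls are
    explicit ``None`` (never a half-typed pair).
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: Mapping[tuple[str, str], tuple[str, str] | None],
    ):
        self.individual_ids = list(individual_ids)
        self.locus_ids = list(locus_ids)
        self._calls = np.empty((len(self.individual_ids), len(self.locus_ids)), dtype=object)
        self._ind_index = {ind: i for i, ind in enumerate(self.individual_ids)}
        self._locus_index = {loc: j for j, loc in enumerate(self.locus_ids)}
        if len(self._ind_index) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(self._locus_index) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        for ind in self.individual_ids:
            for loc in self.locus_ids:
                call = calls.get((ind, loc))
                if call is not None:
                    a, b = call
                    call = (str(a).strip(), str(b).strip())
                self._calls[self._ind_index[ind], self._locus_index[loc]] = call

    @property
    def shape(self) -> tuple[int, int]:
        return self._calls.shape

    def call(self, individual: str, locus: str) -> tuple[str, str] | None:
        return self._calls[self._ind_index[individual], self._locus_index[locus]]

    def locus_calls(self, locus: str) -> list[tuple[str, str] | None]:
        """Calls at one locus in individual order."""
        return list(self._calls[:, self._locus_index[locus]])

    def individual_calls(self, individual: str) -> list[tuple[str, str] | None]:
        return list(self._calls[self._ind_index[individual], :])

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to (possibly repeated) loci. Repeated loci
        are relabelled ``locus.k`` so bootstrap resamples stay addressable."""
        new_ids = []
        seen: dict[str, int] = {}
        cols = []
        for loc in loci:
            k = seen.get(loc, 0)
            seen[loc] = k + 1
            new_ids.append(loc if k == 0 else f"{loc}.{k}")
            cols.append(self._locus_index[loc])
        calls = {}
        for ind in self.individual_ids:
            i = self._ind_index[ind]
            for name, j in zip(new_ids, cols):
                calls[(ind, name)] = self._calls[i, j]
        return GenotypeMatrix(self.individual_ids, new_ids, calls)


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ["entry", "role", "line", "tester", "rep", "block"]


def read_phenotypes(path, trait_list: Sequence[str]) -> tuple[TrialDesign, list[PlotRecord]]:
    """Read a plot-level phenotype CSV and infer the trial design.

    The file needs columns ``entry, role, line, tester, rep, block`` followed
    by one column per trait. The design (lines, testers, replicate count,
    checks) is inferred from the distinct identifiers present. Any
    referential-integrity problem is rejected with the offending row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty phenotype file")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    absent = [t for t in trait_list if t not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing trait columns {absent}")

    line_ids, tester_ids, check_ids = [], [], []
    rows = []
    seen_entry_rep = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        d = row._asdict()
        role = d["role"]
        if role not in ROLES:
            raise ValueError(f"{path} row {i}: unknown role {role!r}")
        entry = d["entry"]
        try:
            rep = int(d["rep"])
        except ValueError:
            raise ValueError(f"{path} row {i}: non-integer rep {d['rep']!r}") from None
        key = (entry, rep)
        if key in seen_entry_rep:
            raise ValueError(f"{path} row {i}: duplicate (entry, rep) {key}")
        seen_entry_rep.add(key)
        traits = {}
        for tname in trait_list:
            cell = d[tname]
            if cell == "":
                continue  # missing plot value
            try:
                traits[tname] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path} row {i}: non-numeric value {cell!r} for trait {tname}"
                ) from None
        if role == "line_parent" and entry not in line_ids:
            line_ids.append(entry)
        elif role == "tester_parent" and entry not in tester_ids:
            tester_ids.append(entry)
        elif role == "check" and entry not in check_ids:
            check_ids.append(entry)
        rows.append((i, entry, role, d["line"], d["tester"], rep, d["block"], traits))

    # Parents declared by their own rows take precedence; a crosses-only
    # file infers the parent sets from the cross rows instead.
    declared_lines, declared_testers = bool(line_ids), bool(tester_ids)
    if not declared_lines:
        line_ids = list(dict.fromkeys(r[3] for r in rows if r[2] == "cross"))
    if not declared_testers:
        tester_ids = list(dict.fromkeys(r[4] for r in rows if r[2] == "cross"))

    records = []
    for i, entry, role, line, tester, rep, block, traits in rows:
        parents = None
        if role == "cross":
            if declared_lines and line not in line_ids:
                raise ValueError(f"{path} row {i}: cross references undeclared line {line!r}")
            if declared_testers and tester not in tester_ids:
                raise ValueError(f"{path} row {i}: cross references undeclared tester {tester!r}")
            parents = (line, tester)
        records.append(
            PlotRecord(entry=entry, role=role, rep=rep, traits=traits,
                       cross_parents=parents, block=block or None)
        )
    design = TrialDesign(
        line_ids=tuple(line_ids),
        tester_ids=tuple(tester_ids),
        n_reps=int(df["rep"].astype(int).max()),
        check_ids=tuple(check_ids),
    )
    return design, records


def write_phenotypes(path, records: Sequence[PlotRecord], trait_list: Sequence[str]) -> None:
    """Write plot records in the CSV dialect :func:`read_phenotypes` reads."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_REQUIRED_COLS + list(trait_list))
        for rec in records:
            line, tester = rec.cross_parents if rec.cross_parents else ("", "")
            cells = [rec.entry, rec.role, line, tester, rec.rep, rec.block or ""]
            for tname in trait_list:
                v = rec.traits.get(tname)
                cells.append("" if v is None else repr(float(v)))
            w.writerow(cells)


def entry_means(records: Sequence[PlotRecord], trait: str) -> EntryMeans:
    """Arithmetic mean per entry over replicates; missing plots reduce the
    divisor."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    present = False
    for rec in records:
        if trait in rec.traits:
            present = True
            sums[rec.entry] = sums.get(rec.entry, 0.0) + rec.traits[trait]
            counts[rec.entry] = counts.get(rec.entry, 0) + 1
    if not present:
        raise ValueError(f"trait {trait!r} absent from records")
    return EntryMeans(trait, {e: sums[e] / counts[e] for e in sums}, counts)


def check_balance(records: Sequence[PlotRecord], design: TrialDesign) -> list[str]:
    """Report deviations from the full balanced layout: every parent, every
    cross and every check present exactly once per replicate. Empty list
    means balanced."""
    expected = {}
    for rep in range(1, design.r + 1):
        for li in design.line_ids:
            expected[(li, rep)] = 0
        for tj in design.tester_ids:
            expected[(tj, rep)] = 0
        for li, tj in design.cross_ids():
            expected[(design.cross_label(li, tj), rep)] = 0
        for c in design.check_ids:
            expected[(c, rep)] = 0
    problems = []
    for rec in records:
        key = (rec.entry, rec.rep)
        if key not in expected:
            problems.append(f"unexpected plot {key}")
        else:
            expected[key] += 1
    for key, n in expected.items():
        if n != 1:
            problems.append(f"plot {key} observed {n} times (expected 1)")
    return problems


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "slash_pair", missing: str = "NA") -> GenotypeMatrix:
    """Read a codominant SSR genotype CSV.

    Two dialects: ``slash_pair`` has one column per locus with ``a/b`` calls;
    ``two_column`` has two columns per locus named ``<locus>.1``/``<locus>.2``.
    A call with one allele present and the other missing is rejected.
    """
    if dialect not in ("slash_pair", "two_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty or df.columns[0] != "individual":
        raise ValueError(f"{path}: first column must be 'individual'")
    individuals = list(df["individual"])
    calls: dict[tuple[str, str], tuple[str, str] | None] = {}
    if dialect == "slash_pair":
        loci = [c for c in df.columns if c != "individual"]
        for ind, row in zip(individuals, df.itertuples(index=False)):
            for loc in loci:
                cell = getattr(row, "_asdict")()[loc].strip()
                if cell == missing or cell == "":
                    calls[(ind, loc)] = None
                else:
                    parts = cell.split("/")
                    if len(parts) != 2:
                        raise ValueError(f"{path}: malformed call {cell!r} at ({ind}, {loc})")
                    a, b = parts[0].strip(), parts[1].strip()
                    if (a == missing) != (b == missing):
                        raise ValueError(f"{path}: half-missing call at ({ind}, {loc})")
                    calls[(ind, loc)] = None if a == missing else (a, b)
    else:
        cols = [c for c in df.columns if c != "individual"]
        loci = []
        for c in cols:
            base = c.rsplit(".", 1)[0]
            if base not in loci:
                loci.append(base)
        for base in loci:
            if f"{base}.1" not in df.columns or f"{base}.2" not in df.columns:
                raise ValueError(f"{path}: locus {base!r} lacks paired .1/.2 columns")
        for ind, (_, row) in zip(individuals, df.iterrows()):
            for base in loci:
                a = row[f"{base}.1"].strip()
                b = row[f"{base}.2"].strip()
                a_miss = a in (missing, "")
                b_miss = b in (missing, "")
                if a_miss != b_miss:
                    raise ValueError(f"{path}: half-missing call at ({ind}, {base})")
                calls[(ind, base)] = None if a_miss else (a, b)
    return GenotypeMatrix(individuals, loci, calls)


def write_genotypes(path, gm: GenotypeMatrix, dialect: str = "slash_pair",
                    missing: str = "NA") -> None:
    if dialect not in ("slash_pair", "two_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "slash_pair":
            w.writerow(["individual"] + gm.locus_ids)
            for ind in gm.individual_ids:
                cells = [ind]
                for call in gm.individual_calls(ind):
                    cells.append(missing if call is None else f"{call[0]}/{call[1]}")
                w.writerow(cells)
        else:
            header = ["individual"]
            for loc in gm.locus_ids:
                header += [f"{loc}.1", f"{loc}.2"]
            w.writerow(header)
            for ind in gm.individual_ids:
                cells = [ind]
                for call in gm.individual_calls(ind):
                    cells += [missing, missing] if call is None else [call[0], call[1]]
                w.writerow(cells)


# ---------------------------------------------------------------------------
# Fixture tables (printed-table transcriptions shipped with the package)
# ---------------------------------------------------------------------------

_FIXTURE_SCHEMAS = {
    "mean_squares": ["source", "df"],
    "variance_components": ["component"],
    "locus_stats": ["locus", "LG", "Ho", "He", "N", "PIC"],
}


def read_fixture_table(path, schema: str) -> pd.DataFrame:
    """Read a schema-conformant fixture CSV, preserving printed labels."""
    if schema not in _FIXTURE_SCHEMAS:
        raise ValueError(f"unknown fixture schema {schema!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty fixture file") from None
    required = _FIXTURE_SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fixture missing columns {missing} for schema {schema}")
    if schema == "mean_squares":
        df = df.set_index("source")
    elif schema == "variance_components":
        df = df.set_index("component")
    return df
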