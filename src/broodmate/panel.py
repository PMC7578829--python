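"""Data model and I/O for multilocus diploid genotype tables.

The native table layout mirrors the fragment-analysis exports commonly fed to
broodstock-management software: four leading metadata columns (group,
population, sex, individual ID) followed by two adjacent allele columns per
locus.  Alleles are positive integers (microsatellite fragment lengths in bp,
or arbitrary codes — SNPs work if their alleles are numbered); 0 or a blank
cell is the missing-data sentinel.  A genotype is an unordered pair: either
both allele copies are called or both are missing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Genotype",
    "Individual",
    "GenotypePanel",
    "Issue",
    "PanelError",
    "ParseError",
    "ValidationError",
    "UsageError",
    "UndefinedStatisticError",
    "genotype",
    "read_panel",
    "write_panel",
    "validate_panel",
    "MALE",
    "FEMALE",
    "DEFAULT_SEX_ALIASES",
]

MALE = "male"
FEMALE = "female"

#: Case-insensitive sex-label aliases accepted on input.
DEFAULT_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
}

#: A called genotype is a sorted (a1, a2) tuple of positive integer allele
#: codes; a missing genotype is None.  Sorting makes the pair unordered.
Genotype = Optional[tuple[int, int]]


class PanelError(Exception):
    """Base class for genotype-table problems."""


class ParseError(PanelError):
    """The input file does not follow the expected table layout."""


class ValidationError(PanelError):
    """The table parsed but violates a panel invariant."""


class UsageError(PanelError):
    """The caller asked for something the data cannot support."""


class UndefinedStatisticError(PanelError):
    """A statistic was requested where no called data exists."""


def genotype(a1, a2) -> Genotype:
    """Build a validated unordered genotype from two allele fields.

    ``0``, ``None`` or blank means missing; both copies must be called or
    both missing (half-calls raise :class:`ValidationError`).
    """
    def _one(x):
        if x is None:
            return None
        if isinstance(x, str):
            x = x.strip()
            if x == "":
                return None
        v = int(x)
        if v < 0:
            raise ValidationError(f"negative allele code {v!r}")
        return None if v == 0 else v

    v1, v2 = _one(a1), _one(a2)
    if (v1 is None) != (v2 is None):
        raise ValidationError(f"half-called genotype ({a1!r}, {a2!r})")
    if v1 is None:
        return None
    return (v1, v2) if v1 <= v2 else (v2, v1)


@dataclass(frozen=True)
class Individual:
    """One genotyped candidate: ID, sex, origin labels and its genotypes."""

    id: str
    sex: str
    group: str
    population: str
    genotypes: tuple[Genotype, ...]

    def genotype_at(self, locus_index: int) -> Genotype:
        return self.genotypes[locus_index]


@dataclass
class GenotypePanel:
    """A validated table of individuals typed at a shared set of loci."""

    locus_names: tuple[str, ...]
    individuals: tuple[Individual, ...]

    def __post_init__(self):
        self.locus_names = tuple(self.locus_names)
        self.individuals = tuple(self.individuals)
        issues = [i for i in validate_panel(self, _check_sexes=False)
                  if i.severity == "error"]
        if issues:
            raise ValidationError("; ".join(i.message for i in issues))
        self._locus_index = {n: i for i, n in enumerate(self.locus_names)}
        self._by_id = {ind.id: ind for ind in self.individuals}

    # -- lookups ---------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def locus_index(self, locus: str) -> int:
        try:
            return self._locus_index[locus]
        except KeyError:
            raise UsageError(f"unknown locus {locus!r}") from None

    def individual(self, id_: str) -> Individual:
        try:
            return self._by_id[id_]
        except KeyError:
            raise UsageError(f"unknown individual ID {id_!r}") from None

    def males(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == MALE]

    def females(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == FEMALE]

    def subset(self, ids: Iterable[str]) -> "GenotypePanel":
        """New panel restricted to the named individuals (file order kept)."""
        wanted = set(ids)
        missing = wanted - {i.id for i in self.individuals}
        if missing:
            raise UsageError(f"unknown individual IDs: {sorted(missing)}")
        return GenotypePanel(
            self.locus_names,
            tuple(i for i in self.individuals if i.id in wanted),
        )

    def genotypes_at(self, locus: str) -> list[Genotype]:
        k = self.locus_index(locus)
        return [ind.genotypes[k] for ind in self.individuals]

    def digest(self) -> str:
        """Stable content hash of the panel (for run logs)."""
        h = hashlib.sha256()
        h.update("|".join(self.locus_names).encode())
        for ind in self.individuals:
            h.update(f"{ind.id},{ind.sex},{ind.genotypes}".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class Issue:
    severity: str          # "error" or "warning"
    individual_id: Optional[str]
    locus: Optional[str]
    message: str


def validate_panel(panel: GenotypePanel, _check_sexes: bool = True) -> list[Issue]:
    """Collect invariant violations without raising or mutating.

    Errors: duplicate IDs, duplicate/empty locus names, genotype-row length
    mismatch, and (when ``_check_sexes``) a sex missing entirely — downstream
    selection needs at least one male and one female.
    """
    issues: list[Issue] = []
    seen_ids: set[str] = set()
    names = panel.locus_names
    if len(set(names)) != len(names):
        issues.append(Issue("error", None, None, "duplicate locus names"))
    for n in names:
        if not str(n).strip():
            issues.append(Issue("error", None, n, "empty locus name"))
    for ind in panel.individuals:
        if ind.id in seen_ids:
            issues.append(Issue("error", ind.id, None, f"duplicate ID {ind.id!r}"))
        seen_ids.add(ind.id)
        if ind.sex not in (MALE, FEMALE):
            issues.append(Issue("error", ind.id, None,
                                f"invalid sex {ind.sex!r} for {ind.id!r}"))
        if len(ind.genotypes) != len(names):
            issues.append(Issue(
                "error", ind.id, None,
                f"{ind.id!r} has {len(ind.genotypes)} genotypes for "
                f"{len(names)} loci"))
    if _check_sexes:
        sexes = {i.sex for i in panel.individuals}
        if MALE not in sexes:
            issues.append(Issue("error", None, None, "panel contains no males"))
        if FEMALE not in sexes:
            issues.append(Issue("error", None, None, "panel contains no females"))
    return issues


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DELIMS = {"comma": ",", "tab": "\t", "semicolon": ";"}


def _resolve_delim(delimiter: Optional[str], path: Optional[Path] = None) -> str:
    if delimiter in _DELIMS:
        return _DELIMS[delimiter]
    if delimiter is not None:
        return delimiter
    if path is not None:  # sniff from the header line
        head = Path(path).open().readline()
        for d in ("\t", ";", ","):
            if d in head:
                return d
    return ","


def read_panel(path, delimiter: Optional[str] = None,
               sex_aliases: Optional[dict] = None) -> GenotypePanel:
    """Read a native genotype table.

    Layout: header row with four metadata labels then the locus names (each
    locus name may appear once over its two columns — the second cell blank —
    or repeated on both); data rows are group, population, sex, ID, then two
    allele fields per locus.  Missing alleles are 0 or blank.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    delim = _resolve_delim(delimiter, path)
    aliases = {k.lower(): v for k, v in (sex_aliases or DEFAULT_SEX_ALIASES).items()}

    try:
        df = pd.read_csv(path, sep=delim, header=None, dtype=str,
                         skip_blank_lines=True, engine="python")
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {e}") from e
    if df.shape[0] < 2:
        raise ParseError(f"{path}: need a header row and at least one individual")
    if df.shape[1] < 6 or (df.shape[1] - 4) % 2 != 0:
        raise ParseError(
            f"{path}: expected 4 metadata columns plus 2 columns per locus, "
            f"got {df.shape[1]} columns")

    header = df.iloc[0].tolist()
    n_loci = (df.shape[1] - 4) // 2
    locus_names = []
    for k in range(n_loci):
        a = header[4 + 2 * k]
        b = header[5 + 2 * k]
        name = (a if isinstance(a, str) and a.strip() else b)
        if name is None or not str(name).strip():
            raise ParseError(f"{path}: locus {k + 1} has no name in the header")
        locus_names.append(str(name).strip())

    individuals = []
    for r in range(1, df.shape[0]):
        row = df.iloc[r].tolist()
        if all(pd.isna(x) or str(x).strip() == "" for x in row):
            continue
        group, popn, sex_raw, id_ = (
            "" if pd.isna(x) else str(x).strip() for x in row[:4])
        if not id_:
            raise ParseError(f"{path} row {r + 1}: empty individual ID")
        sex = aliases.get(sex_raw.lower())
        if sex is None:
            raise ValidationError(
                f"{path} row {r + 1}: unknown sex label {sex_raw!r}")
        gts = []
        for k, locus in enumerate(locus_names):
            a = row[4 + 2 * k]
            b = row[5 + 2 * k]
            a = None if pd.isna(a) else a
            b = None if pd.isna(b) else b
            try:
                gts.append(genotype(a, b))
            except ValidationError as e:
                raise ValidationError(
                    f"{path} individual {id_!r} locus {locus!r}: {e}") from None
        individuals.append(Individual(id_, sex, group, popn, tuple(gts)))

    ids = [i.id for i in individuals]
    dups = {x for x in ids if ids.count(x) > 1}
    if dups:
        raise ValidationError(f"{path}: duplicate individual IDs {sorted(dups)}")
    return GenotypePanel(tuple(locus_names), tuple(individuals))


def write_panel(panel: GenotypePanel, path, format: str = "native-table",
                delimiter: Optional[str] = None) -> None:
    """Write a panel as the native table or as a Genepop file.

    Native output is bit-stable for a fixed panel.  Genepop encodes each
    allele as a zero-padded 3-digit code (missing = 000) in a single POP
    block; allele codes above 999 cannot be represented and raise.
    """
    path = Path(path)
    bad = [i for i in validate_panel(panel, _check_sexes=False)
           if i.severity == "error"]
    if bad:
        raise ValidationError("cannot export invalid panel: "
                              + "; ".join(i.message for i in bad))
    if format == "native-table":
        delim = _resolve_delim(delimiter)
        lines = [delim.join(
            ["group", "population", "sex", "id"]
            + [n for name in panel.locus_names for n in (name, name)])]
        for ind in panel.individuals:
            cells = [ind.group, ind.population, ind.sex, ind.id]
            for gt in ind.genotypes:
                cells += ["0", "0"] if gt is None else [str(gt[0]), str(gt[1])]
            lines.append(delim.join(cells))
        path.write_text("\n".join(lines) + "\n")
    elif format == "genepop":
        for ind in panel.individuals:
            for gt, locus in zip(ind.genotypes, panel.locus_names):
                if gt is not None and max(gt) > 999:
                    raise UsageError(
                        f"allele code {max(gt)} at {locus!r} exceeds Genepop's "
                        "3-digit range; recode alleles (e.g. subtract a base "
                        "fragment length) before export")
        lines = ["broodmate genotype panel export"]
        lines += list(panel.locus_names)
        lines.append("POP")
        for ind in panel.individuals:
            codes = ["000000" if gt is None else f"{gt[0]:03d}{gt[1]:03d}"
                     for gt in ind.genotypes]
            lines.append(f"{ind.id}, " + " ".join(codes))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise UsageError(f"unknown export format {format!r}")
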