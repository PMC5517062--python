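"""Strain and phenotype dictionaries for dictionary-based entity recognition.

Mouse and rat strain dictionaries are compiled from MGD/RGD-style listings:
each entry carries a preferred name, strain type, synonyms, and substrains.
Substrain designations append laboratory codes to the parental strain after a
slash (AKR/NCr is the Charles River substrain of AKR), so substrains of inbred
strains fold onto their parent; hybrid/congenic/coisogenic names stay as
individual entries. Matching uses keys that depend only on alphanumeric
characters ("ob-ob mouse" and "ob/ob mouse" share the key ``obobmouse``),
which absorbs the punctuation variation typical of curator text.

The phenotype dictionary indexes term labels and exact synonyms of OBO
ontologies (symptom, phenotype, trait, clinical-measurement, disease and
behavior vocabularies), with a minimum-length filter and a blocklist guarding
against ontology terms that are generic English words.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "match_key",
    "parse_substrain_parent",
    "StrainEntry",
    "StrainDictionary",
    "load_strain_listing",
    "compile_strain_dictionary",
    "PhenotypeDictionary",
    "load_phenotype_dictionary",
]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def match_key(s: str) -> str:
    """Lower-case and strip all non-alphanumeric characters."""
    return _NON_ALNUM.sub("", s.lower())


def parse_substrain_parent(name: str, known_basic: Iterable[str] | None = None) -> str:
    """Parent strain of a substrain designation.

    Laboratory-code segments after the first "/" are removed iff the remaining
    prefix is a known basic strain (by alphanumeric key); otherwise the name is
    returned unchanged, which protects hybrid names like "B6D2F1". With no
    ``known_basic`` context any slash-suffixed name is stripped. Idempotent.
    """
    if "/" not in name:
        return name
    prefix = name.split("/", 1)[0].strip()
    if not prefix:
        return name
    if known_basic is not None:
        keys = {k if isinstance(k, str) and k == match_key(k) else match_key(k) for k in known_basic}
        if match_key(prefix) not in keys:
            return name
    return prefix


@dataclass
class StrainEntry:
    preferred_name: str
    species: str  # "mouse" | "rat"
    strain_type: str = "other"  # inbred | outbred | hybrid | congenic | coisogenic | other
    synonyms: set[str] = field(default_factory=set)
    substrains: set[str] = field(default_factory=set)

    def all_names(self) -> set[str]:
        return {self.preferred_name} | self.synonyms | self.substrains


class StrainDictionary:
    """Compiled strain dictionary with an alphanumeric-key match index.

    Every name, synonym and substrain is indexed both bare and with the
    species word appended, so "sprague dawley" and "Sprague-Dawley rat" both
    resolve. A key mapping to two different entries is a build failure.
    """

    def __init__(self, entries: list[StrainEntry]):
        self.entries = sorted(entries, key=lambda e: (e.species, e.preferred_name))
        self.key_index: dict[str, StrainEntry] = {}
        collisions: dict[str, set[str]] = {}
        for entry in self.entries:
            sp_words = {"mouse": ("mouse", "mice"), "rat": ("rat", "rats")}[entry.species]
            for name in entry.all_names():
                for key in (match_key(name), *(match_key(f"{name} {w}") for w in sp_words)):
                    if not key:
                        continue
                    prev = self.key_index.get(key)
                    if prev is not None and prev is not entry:
                        collisions.setdefault(key, set()).update(
                            {prev.preferred_name, entry.preferred_name}
                        )
                    self.key_index[key] = entry
        if collisions:
            detail = "; ".join(f"{k} -> {sorted(v)}" for k, v in sorted(collisions.items()))
            raise ValueError(f"strain dictionary key collisions: {detail}")
        self._basic_keys = {match_key(e.preferred_name) for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, text: str) -> StrainEntry | None:
        """Resolve a surface string; unseen substrains of known basic strains
        fall back to the parsed parent."""
        key = match_key(text)
        entry = self.key_index.get(key)
        if entry is not None:
            return entry
        if "/" in text:
            parent = parse_substrain_parent(text, self._basic_keys)
            if parent != text:
                return self.key_index.get(match_key(parent))
        return None

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "vivominer-strain-dictionary/1",
            "entries": [
                {
                    "preferred_name": e.preferred_name,
                    "species": e.species,
                    "strain_type": e.strain_type,
                    "synonyms": sorted(e.synonyms),
                    "substrains": sorted(e.substrains),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StrainDictionary":
        payload = json.loads(Path(path).read_text())
        entries = [
            StrainEntry(
                d["preferred_name"], d["species"], d["strain_type"],
                set(d["synonyms"]), set(d["substrains"]),
            )
            for d in payload["entries"]
        ]
        return cls(entries)


def load_strain_listing(path: str | Path | None = None) -> pd.DataFrame:
    """Read a strain listing table (species, name, strain_type, synonyms,
    substrains; '|'-separated multi-values, '#' comments).

    With no path, the bundled synthetic mini-listing is returned — a small
    curated stand-in for full MGD/RGD exports, sufficient for the synthetic
    corpus and tests.
    """
    if path is None:
        with resources.as_file(
            resources.files("vivominer.data").joinpath("strains_synthetic.tsv")
        ) as p:
            return load_strain_listing(p)
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["species", "name", "strain_type", "synonyms", "substrains"],
        dtype=str, keep_default_na=False,
    )
    return df


def compile_strain_dictionary(
    listing: pd.DataFrame, species: str | None = None
) -> StrainDictionary:
    """Build a :class:`StrainDictionary` from a listing table.

    Substrains fold under their parent only for inbred strains whose "/"
    prefix resolves to a listed basic strain; other slash-containing names are
    kept intact.
    """
    rows = listing if species is None else listing[listing["species"] == species]
    entries: dict[tuple[str, str], StrainEntry] = {}
    for _, row in rows.iterrows():
        name = row["name"].strip()
        if not name:
            continue
        entry = StrainEntry(
            preferred_name=name,
            species=row["species"].strip(),
            strain_type=(row.get("strain_type") or "other").strip() or "other",
            synonyms={s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()},
            substrains={s.strip() for s in (row.get("substrains") or "").split("|") if s.strip()},
        )
        entry.synonyms.discard(entry.preferred_name)
        entries[(entry.species, name)] = entry
    # fold listed names that parse as substrains of a listed inbred basic strain
    basics = {
        (e.species, match_key(e.preferred_name)): e
        for e in entries.values()
    }
    folded: list[StrainEntry] = []
    for (sp, name), entry in entries.items():
        parent_name = parse_substrain_parent(name, [k for s, k in basics if s == sp])
        parent = basics.get((sp, match_key(parent_name)))
        if parent is not None and parent is not entry and parent.strain_type == "inbred":
            parent.substrains.add(name)
            parent.substrains.update(entry.synonyms)
            parent.substrains.update(entry.substrains)
        else:
            folded.append(entry)
    return StrainDictionary(folded)


# ---------------------------------------------------------------------------
# Phenotype dictionary
# ---------------------------------------------------------------------------

#: generic English words that happen to be ontology term labels
DEFAULT_BLOCKLIST = frozenset({
    "activity", "quality", "behavior", "behaviour", "process", "trait",
    "disease", "increase", "decrease", "all", "size", "rate", "time",
})


class PhenotypeDictionary:
    """Match-key index of phenotype term labels and exact synonyms.

    Duplicate keys across ontologies merge, keeping all sources; the first
    label seen (in load order) is the preferred label.
    """

    def __init__(self, min_len: int = 3, blocklist: frozenset[str] = DEFAULT_BLOCKLIST):
        self.min_len = min_len
        self.blocklist = frozenset(w.lower() for w in blocklist)
        self.key_index: dict[str, str] = {}
        self.sources: dict[str, set[str]] = {}

    def add_term(self, label: str, source: str = "custom", synonyms: Iterable[str] = ()) -> None:
        for name in (label, *synonyms):
            name = name.strip()
            if len(name) < self.min_len or name.lower() in self.blocklist:
                continue
            key = match_key(name)
            if not key:
                continue
            self.key_index.setdefault(key, label)
            self.sources.setdefault(key, set()).add(source)

    def lookup(self, text: str) -> str | None:
        return self.key_index.get(match_key(text))

    def __len__(self) -> int:
        return len(self.key_index)

    @classmethod
    def from_terms(cls, terms: Iterable[str], source: str = "custom", **kw) -> "PhenotypeDictionary":
        d = cls(**kw)
        for t in terms:
            d.add_term(t, source)
        return d

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "vivominer-phenotype-dictionary/1",
            "min_len": self.min_len,
            "terms": {
                k: {"label": v, "sources": sorted(self.sources.get(k, set()))}
                for k, v in sorted(self.key_index.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeDictionary":
        payload = json.loads(Path(path).read_text())
        d = cls(min_len=payload.get("min_len", 3))
        for key, info in payload["terms"].items():
            d.key_index[key] = info["label"]
            d.sources[key] = set(info["sources"])
        return d


_EXACT_SYN = re.compile(r'"((?:[^"\\]|\\.)*)"\s+EXACT')
_ANY_SYN = re.compile(r'"((?:[^"\\]|\\.)*)"')


def load_phenotype_dictionary(
    obo_paths: Iterable[str | Path],
    min_len: int = 3,
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST,
    synonym_scope: str = "exact",
) -> PhenotypeDictionary:
    """Compile a phenotype dictionary from OBO ontology files.

    Non-obsolete term labels plus synonyms are indexed. ``synonym_scope``
    "exact" (default) uses only EXACT synonyms; "all" widens to every synonym
    scope. An unparseable file raises with its name.
    """
    import obonet

    d = PhenotypeDictionary(min_len=min_len, blocklist=blocklist)
    syn_re = _EXACT_SYN if synonym_scope == "exact" else _ANY_SYN
    for path in obo_paths:
        try:
            graph = obonet.read_obo(str(path))
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ValueError(f"cannot parse OBO file {path}: {exc}") from exc
        source = Path(path).stem
        for _, data in graph.nodes(data=True):
            label = data.get("name")
            if not label:
                continue
            synonyms = []
            for raw in data.get("synonym", []):
                m = syn_re.match(raw)
                if m:
                    synonyms.append(m.group(1).replace('\\"', '"'))
            d.add_term(label, source, synonyms)
    return d
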