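"""Synthetic corpus generator emulating curator-written bioassay descriptions.

Every pipeline stage needs realistic inputs: short (10–30 word) descriptions
of the canonical form

    "Inhibition of <stimulus>-induced <phenotype> in <strain> <species>
     at <dose> mg/kg, <route> after <time> hrs"

with gold entity spans, several near-duplicate assays per source document
(same experiment, different dose/timing — the structure that motivates
document-based cross-validation splits), and drug/ATC labels whose class
vocabularies have controllable separation (``class_vocab_overlap`` 0 = fully
class-specific stimuli/phenotypes, 1 = all classes share one vocabulary, so
classifier difficulty is tunable down to chance).

Vocabularies are seeded with the entity names a practitioner would recognize
(maximal electroshock, carrageenan, P388 leukemia, streptozotocin, ZDF rat…)
so fixtures read realistically. Dose and time numerals are drawn log-uniformly
within plausible ranges and are never part of gold spans. Everything is
reproducible from (config, seed); the generator ledger records every planted
truth (classes, entities, per-name distinct-assay counts, synonym pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import AssayRecord, CompoundRecord
from .lexicon import PhenotypeDictionary, StrainDictionary, compile_strain_dictionary, load_strain_listing
from .ner import AnnotatedDescription, EntityMention, write_brat

__all__ = [
    "ClassVocabulary",
    "SyntheticConfig",
    "SyntheticCorpus",
    "DEFAULT_CLASS_VOCABULARIES",
    "render_description",
    "generate_corpus",
]


@dataclass
class ClassVocabulary:
    """Per-class entity tables: stimuli (induced-model triggers), phenotypes,
    strains (surface, species), and drugs (name, ATC codes, max_phase)."""

    stimuli: list[str]
    phenotypes: list[str]
    strains: list[tuple[str, str]]  # (strain preferred name, species)
    drugs: list[tuple[str, tuple[str, ...]]]  # (name, atc codes)
    effects: list[str] = field(default_factory=lambda: ["Inhibition", "Reduction", "Suppression"])


DEFAULT_CLASS_VOCABULARIES: dict[str, ClassVocabulary] = {
    "antiepileptics": ClassVocabulary(
        stimuli=["maximal electroshock", "pentylenetetrazole", "bicuculline", "picrotoxin", "strychnine"],
        phenotypes=["seizures", "clonic seizures", "convulsions", "tonic extension", "hind limb extension"],
        strains=[("CF-1", "mouse"), ("NMRI", "mouse"), ("Swiss", "mouse"), ("Wistar", "rat")],
        drugs=[
            ("phenytoin", ("N03AB02",)), ("carbamazepine", ("N03AF01",)),
            ("phenobarbital", ("N03AA02",)), ("ethosuximide", ("N03AD01",)),
            ("valproic acid", ("N03AG01",)),
        ],
        effects=["Inhibition", "Protection", "Suppression"],
    ),
    "psycholeptics": ClassVocabulary(
        stimuli=["apomorphine", "amphetamine", "pentobarbital", "ketamine", "scopolamine"],
        phenotypes=["catalepsy", "locomotor activity", "stereotypic behavior", "climbing behavior", "immobility"],
        strains=[("Sprague Dawley", "rat"), ("Wistar", "rat"), ("ICR", "mouse"), ("Long Evans", "rat")],
        drugs=[
            ("diazepam", ("N05BA01",)), ("haloperidol", ("N05AD01",)),
            ("clozapine", ("N05AH02",)), ("chlorpromazine", ("N05AA01",)),
            ("risperidone", ("N05AX08",)),
        ],
        effects=["Inhibition", "Reduction", "Reversal"],
    ),
    "antineoplastics": ClassVocabulary(
        stimuli=["P388 leukemia", "L1210 leukemia", "B16 melanoma", "M5076 sarcoma", "Ehrlich ascites carcinoma"],
        phenotypes=["life span", "tumor growth", "survival time", "mortality", "tumor volume"],
        strains=[("BALB/c", "mouse"), ("C57BL", "mouse"), ("DBA", "mouse"), ("nude", "mouse")],
        drugs=[
            ("cytarabine", ("L01BC01",)), ("doxorubicin", ("L01DB01",)),
            ("mitomycin", ("L01DC03",)), ("fluorouracil", ("L01BC02",)),
            ("cisplatin", ("L01XA01",)),
        ],
        effects=["Antitumor activity", "Increase", "Inhibition"],
    ),
    "antidiabetics": ClassVocabulary(
        stimuli=["streptozotocin", "alloxan", "glucose", "high-fat diet", "fructose"],
        phenotypes=["blood glucose level", "plasma glucose level", "hyperglycemia", "glucose tolerance", "body weight"],
        strains=[("ZDF", "rat"), ("ob/ob", "mouse"), ("db/db", "mouse"), ("Zucker", "rat")],
        drugs=[
            ("rosiglitazone", ("A10BG02",)), ("metformin", ("A10BA02",)),
            ("glyburide", ("A10BB01",)), ("pioglitazone", ("A10BG03",)),
            ("tolbutamide", ("A10BB03",)),
        ],
        effects=["Reduction", "Decrease", "Antihyperglycemic activity"],
    ),
    "anti_inflammatory": ClassVocabulary(
        stimuli=["carrageenan", "Freund's complete adjuvant", "acetic acid", "TPA", "croton oil"],
        phenotypes=["paw oedema", "arthritis", "swelling", "hyperalgesia", "writhing"],
        strains=[("Sprague Dawley", "rat"), ("Wistar", "rat"), ("Swiss", "mouse"), ("Lewis", "rat")],
        drugs=[
            ("indomethacin", ("M01AB01", "C01EB03", "M02AA23", "S01BC01")),
            ("phenylbutazone", ("M01AA01",)), ("ketoprofen", ("M01AE03",)),
            ("rofecoxib", ("M01AH02",)), ("zomepirac", ("M01AB04",)),
        ],
        effects=["Inhibition", "Anti-inflammatory activity", "Reduction"],
    ),
}

#: phenotype synonym pairs planted interchangeably for embedding tests
DEFAULT_SYNONYM_PAIRS: tuple[tuple[str, str], ...] = (
    ("paw oedema", "paw edema"),
    ("convulsions", "seizures"),
    ("blood glucose level", "glycemia"),
)

#: strain surface-form noise: preferred name -> nonstandard surface variants
STRAIN_SURFACE_VARIANTS: dict[str, list[str]] = {
    "ob/ob": ["ob-ob"],
    "db/db": ["db-db"],
    "C57BL": ["C57BL/6J", "Black 6"],
    "Sprague Dawley": ["Sprague-Dawley"],
    "ZDF": ["Zucker diabetic fatty"],
}

ROUTES = ["subcutaneous", "intraperitoneal", "intravenous", "peroral", "intramuscular"]
ROUTE_ACRONYMS = {"subcutaneous": "sc", "intraperitoneal": "ip", "intravenous": "iv",
                  "peroral": "po", "intramuscular": "im"}


@dataclass
class SyntheticConfig:
    """Generator configuration; ``seed`` is mandatory.

    ``class_vocab_overlap`` in [0, 1] replaces that fraction of class-specific
    stimulus/phenotype/strain/template material with draws from a shared pool
    (1.0 makes every class statistically identical). Noise knobs are rates in
    [0, 1]: ``acronym_rate`` emits route acronyms instead of expansions,
    ``strain_synonym_rate`` emits nonstandard strain surfaces,
    ``synonym_plant_rate`` swaps planted phenotype synonyms in.
    """

    seed: int
    n_documents: int = 120
    assays_per_document: tuple[int, int] = (3, 8)
    classes: Sequence[str] = tuple(DEFAULT_CLASS_VOCABULARIES)
    class_mix: Sequence[float] | None = None
    class_vocab_overlap: float = 0.0
    acronym_rate: float = 0.3
    strain_synonym_rate: float = 0.2
    synonym_plant_rate: float = 0.3
    novel_compound_rate: float = 0.5
    transgenic_rate: float = 0.04
    vocabularies: dict[str, ClassVocabulary] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_CLASS_VOCABULARIES.items()}
    )

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.class_vocab_overlap <= 1:
            raise ValueError("class_vocab_overlap must be in [0, 1]")
        if self.class_mix is not None:
            if len(self.class_mix) != len(self.classes):
                raise ValueError("class_mix length must match classes")
            if abs(sum(self.class_mix) - 1.0) > 1e-9:
                raise ValueError("class_mix must sum to 1")
        lo, hi = self.assays_per_document
        if not (1 <= lo <= hi):
            raise ValueError("invalid assays_per_document range")
        for name in self.classes:
            vocab = self.vocabularies.get(name)
            if vocab is None:
                raise ValueError(f"no vocabulary for class {name!r}")
            if not (vocab.stimuli and vocab.phenotypes and vocab.strains and vocab.drugs):
                raise ValueError(f"class {name!r} has an empty vocabulary table")


@dataclass
class SyntheticCorpus:
    assays: list[AssayRecord]
    compounds: list[CompoundRecord]
    links: list[tuple[str, str]]
    gold: list[AnnotatedDescription]
    ledger: dict

    def strain_dictionary(self) -> StrainDictionary:
        return compile_strain_dictionary(load_strain_listing())

    def phenotype_dictionary(self) -> PhenotypeDictionary:
        return PhenotypeDictionary.from_terms(
            self.ledger["phenotype_vocabulary"], source="synthetic"
        )

    def write_tables(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "assays": out / "assays.tsv",
            "compounds": out / "compounds.tsv",
            "links": out / "links.tsv",
            "gold": out / "gold",
            "ledger": out / "ledger.json",
        }
        pd.DataFrame(
            [(a.assay_id, a.description, a.species, a.document_id, "|".join(a.compound_ids))
             for a in self.assays],
            columns=["assay_id", "description", "species", "document_id", "compound_ids"],
        ).to_csv(paths["assays"], sep="\t", index=False)
        pd.DataFrame(
            [(c.compound_id, c.name, "|".join(c.atc_codes), c.max_phase) for c in self.compounds],
            columns=["compound_id", "name", "atc_codes", "max_phase"],
        ).to_csv(paths["compounds"], sep="\t", index=False)
        pd.DataFrame(self.links, columns=["assay_id", "compound_id"]).to_csv(
            paths["links"], sep="\t", index=False
        )
        write_brat(self.gold, paths["gold"])
        paths["ledger"].write_text(json.dumps(self.ledger, indent=1, default=list))
        return paths


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def render_description(
    effect: str,
    stimulus: str,
    phenotype: str,
    strain: str | None,
    species: str,
    rng: np.random.Generator,
    template: int = 0,
    acronym_rate: float = 0.0,
    strain_norm: str | None = None,
    transgene: str | None = None,
) -> tuple[str, list[EntityMention]]:
    """Assemble one description and its gold mentions (spans into the emitted
    raw text). Dose/time numerals are outside every gold span."""
    dose = f"{_log_uniform(rng, 0.1, 100):.4g}"
    hours = int(rng.integers(1, 25))
    route = ROUTES[int(rng.integers(0, len(ROUTES)))]
    if rng.random() < acronym_rate:
        route = ROUTE_ACRONYMS[route]

    gold: list[EntityMention] = []
    parts: list[str] = []
    pos = 0

    def emit(text: str, cls: str | None = None, normalized: str | None = None):
        nonlocal pos
        if cls is not None:
            gold.append(EntityMention("", cls, text, normalized or text, pos, pos + len(text)))
        parts.append(text)
        pos += len(text)

    if transgene is not None:
        # "Reduction of <phenotype> in <gene> transgenic <species> at ..."
        emit(f"{effect} of ")
        emit(phenotype, "phenotype")
        emit(" in ")
        emit(f"{transgene} transgenic", "transgenic_model", f"{transgene.lower()} transgenic")
        emit(f" {species} at {dose} mg/kg, {route}")
        return "".join(parts), gold

    model_surface = f"{stimulus}-induced"
    trigger = "induced"
    if template == 3:  # tumour-line template
        model_surface = f"{stimulus} inoculated"
        trigger = "inoculated"
    elif stimulus.endswith("diet"):
        model_surface = f"{stimulus}-fed"
        trigger = "fed"
    model_norm = f"{stimulus.lower().replace('-', ' ')} {trigger}"

    if template == 0:
        emit(f"{effect} of ")
        emit(model_surface, "experimental_model", model_norm)
        emit(" ")
        emit(phenotype, "phenotype")
        if strain is not None:
            emit(" in ")
            emit(f"{strain} {species}", "genetic_strain", strain_norm or strain)
        else:
            emit(f" in {species}")
        emit(f" at {dose} mg/kg, {route} after {hours} hrs")
    elif template == 1:
        emit(f"{effect} of ")
        emit(phenotype, "phenotype")
        emit(" in ")
        if strain is not None:
            emit(f"{strain} {species}", "genetic_strain", strain_norm or strain)
        else:
            emit(species)
        emit(" with ")
        emit(model_surface, "experimental_model", model_norm)
        emit(f" condition at {dose} mg/kg, {route}")
    elif template == 2:
        emit("Effect of compound on ")
        emit(model_surface, "experimental_model", model_norm)
        emit(" ")
        emit(phenotype, "phenotype")
        if strain is not None:
            emit(" in ")
            emit(f"{strain} {species}", "genetic_strain", strain_norm or strain)
        else:
            emit(f" in {species}")
        emit(f" at {dose} mg/kg, {route} daily")
    else:  # template == 3
        emit(f"{effect} against ")
        emit(model_surface, "experimental_model", model_norm)
        emit(" in ")
        if strain is not None:
            emit(f"{strain} {species}", "genetic_strain", strain_norm or strain)
        else:
            emit(f"{species}")
        emit(", change in ")
        emit(phenotype, "phenotype")
        emit(f" at {dose} mg/kg, {route} after {hours} hrs")
    return "".join(parts), gold


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate (assay table, compound table, link table, gold BRAT set, ledger).

    Same-document assays share class, template and entity choices and differ in
    dose/timing, reproducing the near-duplicate structure of curated corpora.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = list(config.classes)
    mix = (
        np.array(config.class_mix, dtype=float)
        if config.class_mix is not None
        else np.full(len(classes), 1.0 / len(classes))
    )

    # shared pool for the overlap knob: class 0's tables serve as the pool so
    # overlap=1 collapses every class onto one vocabulary
    pool = config.vocabularies[classes[0]]

    compounds: list[CompoundRecord] = []
    comp_index: dict[str, str] = {}
    for cls in classes:
        for name, codes in config.vocabularies[cls].drugs:
            cid = f"DRUG{len(compounds) + 1:04d}"
            comp_index[name] = cid
            compounds.append(CompoundRecord(cid, name, tuple(codes), 4))
    n_novel = max(1, len(compounds) // 2)
    for i in range(n_novel):
        compounds.append(CompoundRecord(f"CPD{i + 1:05d}", f"compound-{i + 1}", (), 0))
    novel_ids = [c.compound_id for c in compounds if c.max_phase == 0]

    def pick(seq, overlap_pool):
        if config.class_vocab_overlap > 0 and rng.random() < config.class_vocab_overlap:
            seq = overlap_pool
        return seq[int(rng.integers(0, len(seq)))]

    assays: list[AssayRecord] = []
    links: list[tuple[str, str]] = []
    gold_docs: list[AnnotatedDescription] = []
    true_classes: dict[str, str] = {}
    model_counts: dict[str, set[str]] = {}
    strain_counts: dict[str, set[str]] = {}
    phen_counts: dict[str, set[str]] = {}
    synonym_events = 0

    syn_map = {a: b for a, b in DEFAULT_SYNONYM_PAIRS}
    aid = 0
    for doc_i in range(config.n_documents):
        doc_id = f"DOC{doc_i + 1:04d}"
        cls = classes[int(rng.choice(len(classes), p=mix))]
        vocab = config.vocabularies[cls]
        stimulus = pick(vocab.stimuli, pool.stimuli)
        phenotype = pick(vocab.phenotypes, pool.phenotypes)
        strain_name, species = pick(vocab.strains, pool.strains)
        effect = pick(vocab.effects, pool.effects)
        template = (
            3 if cls == "antineoplastics" and config.class_vocab_overlap == 0
            else int(rng.integers(0, 3))
        )
        use_strain = rng.random() < 0.85
        transgenic_doc = rng.random() < config.transgenic_rate
        drug_name = vocab.drugs[int(rng.integers(0, len(vocab.drugs)))][0]

        n_assays = int(rng.integers(config.assays_per_document[0],
                                    config.assays_per_document[1] + 1))
        for _ in range(n_assays):
            aid += 1
            assay_id = f"ASSAY{aid:05d}"
            phen = phenotype
            if phenotype in syn_map and rng.random() < config.synonym_plant_rate:
                phen = syn_map[phenotype]
                synonym_events += 1
            strain_surface = strain_name
            if (
                use_strain
                and strain_name in STRAIN_SURFACE_VARIANTS
                and rng.random() < config.strain_synonym_rate
            ):
                variants = STRAIN_SURFACE_VARIANTS[strain_name]
                strain_surface = variants[int(rng.integers(0, len(variants)))]
            text, gold = render_description(
                effect, stimulus, phen,
                strain_surface if use_strain else None,
                species, rng,
                template=template,
                acronym_rate=config.acronym_rate,
                strain_norm=strain_name,
                transgene="APOA1" if transgenic_doc else None,
            )
            gold = [
                EntityMention(assay_id, m.entity_class, m.surface, m.normalized,
                              m.char_start, m.char_end)
                for m in gold
            ]
            compound_ids = [comp_index[drug_name]]
            if rng.random() < config.novel_compound_rate:
                compound_ids.append(novel_ids[int(rng.integers(0, len(novel_ids)))])
            assays.append(AssayRecord(assay_id, text, species, doc_id, ()))
            links.extend((assay_id, cid) for cid in compound_ids)
            gold_docs.append(AnnotatedDescription(assay_id, text, gold))
            true_classes[assay_id] = cls
            for m in gold:
                target = {
                    "genetic_strain": strain_counts,
                    "phenotype": phen_counts,
                }.get(m.entity_class, model_counts)
                target.setdefault(m.normalized, set()).add(assay_id)

    phen_vocab = sorted(
        {p for cls in classes for p in config.vocabularies[cls].phenotypes}
        | {b for _, b in DEFAULT_SYNONYM_PAIRS}
    )
    ledger = {
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if k != "vocabularies"
        },
        "n_assays": len(assays),
        "n_documents": config.n_documents,
        "true_class": true_classes,
        "model_assay_counts": {k: sorted(v) for k, v in model_counts.items()},
        "strain_assay_counts": {k: sorted(v) for k, v in strain_counts.items()},
        "phenotype_assay_counts": {k: sorted(v) for k, v in phen_counts.items()},
        "synonym_pairs": [list(p) for p in DEFAULT_SYNONYM_PAIRS],
        "n_synonym_events": synonym_events,
        "phenotype_vocabulary": phen_vocab,
    }
    return SyntheticCorpus(assays, compounds, links, gold_docs, ledger)
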