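# afp-triage

A literature-triage toolkit for biocuration teams, modeled on the
author-first-pass workflow used by model-organism databases: newly
published papers are mined for the biological entities and data types they
contain, the corresponding author is asked to validate the machine's
suggestions, and the returned submissions are compared against the
machine output to quantify extraction quality.

It is aimed at curators and text-mining developers who need a
self-contained, testable implementation of that pipeline: every stage runs
on plain-text inputs and controlled vocabularies, with no database or web
dependencies, and a synthetic-fixtures module generates articles, training
corpora and author submissions with known ground truth.

## What it computes

**Entity extraction.** Articles are matched against per-type lexicons
(genes, alleles, strains, transgenes, species) with word-boundary-aware
string matching: a hit may not touch a letter, digit or hyphen, so `lin-3`
never fires inside `lin-39` or `pre-lin-3`. Gene names also match in
all-uppercase protein form (`LIN-3`); species match as full binomials
(*Drosophila melanogaster*), abbreviated binomials (*D. melanogaster*) or
configured common-name aliases ("zebrafish"). An entity is reported when
its in-text mention count reaches the type's threshold —

| type | threshold |
|---|---|
| gene | 2 |
| allele | 2 |
| strain | 1 |
| transgene | 1 |
| species | 10 |

— or when it is mentioned even once in the title. Papers with no genes,
alleles, strains or transgenes are discarded as not curatable.

**Data-type classification.** Eight binary flags (allele sequence change,
anatomic expression, genetic/physical/regulatory interactions, allele,
RNAi and transgene-overexpression phenotypes) come from per-type linear
max-margin classifiers (L2-regularized hinge loss, tf-idf bag-of-words);
a paper is flagged positive when the decision margin `w·x + b > 0`.

**Batch triage.** Weekly runs consume up to 50 queued papers, drop
empty-text and entity-free papers, resolve the corresponding author (first
email address in the text matching the person registry), issue tokenized
notifications, and schedule up to two reminders at ≥30 and ≥60 days.

**Agreement analytics.** For each author submission the toolkit computes
per-type added/removed entity sets and the Jaccard coefficient
J(A, B) = |A∩B| / |A∪B| between extracted and validated lists, plus
confusion-matrix accuracy/precision/recall for flag agreement and
dashboard statistics (response rate, entity-count distributions, genes
per submission).

## Worked example

```python
from afp.corpus import Article, EntityType, LexiconEntry
from afp.extraction import MatchRuleSet, extract_entities
from afp.analytics import Submission, diff_submission
from afp.classify import DataTypeLabel

lexicons = {
    EntityType.GENE: [
        LexiconEntry(EntityType.GENE, "WBGene00002992", "lin-3", ("F36H1.4",)),
        LexiconEntry(EntityType.GENE, "WBGene00002299", "let-23"),
    ],
    EntityType.ALLELE: [LexiconEntry(EntityType.ALLELE, "WBVar00088378", "sy53")],
    EntityType.STRAIN: [LexiconEntry(EntityType.STRAIN, "WBStrain00004309", "CB1417")],
}

article = Article(
    paper_id="WBPaper00012345",
    title="Induction of vulval fates in CB1417",
    abstract="The EGF ligand LIN-3 activates LET-23 signaling.",
    body="We isolated sy53 and a second sy53 allele. lin-3 (F36H1.4) acts upstream.",
)

result = extract_entities(article, lexicons, MatchRuleSet())
for t in (EntityType.GENE, EntityType.ALLELE, EntityType.STRAIN):
    for m in result.included.get(t, ()):
        print(f"{t.value:8s} {m.canonical_id:16s} title={m.title_count} text={m.text_count}")
```

```
gene     WBGene00002992   title=0 text=3
allele   WBVar00088378    title=0 text=2
strain   WBStrain00004309 title=1 text=0
```

`lin-3` is included with three mentions (`LIN-3` via the protein-case
rule, `lin-3`, and its sequence-name synonym `F36H1.4` all count toward
the same entry); `sy53` meets the allele threshold of 2; `CB1417` is
included on a single title mention alone. `let-23` appears only once
(`LET-23`) — below the gene threshold — and is correctly left out.

An author validating this paper might add the missed gene:

```python
submission = Submission(
    paper_id="WBPaper00012345", person_id="WBPerson101", status="complete",
    final_entities={
        EntityType.GENE: frozenset({"WBGene00002992", "WBGene00002299"}),
        EntityType.ALLELE: frozenset({"WBVar00088378"}),
        EntityType.STRAIN: frozenset({"WBStrain00004309"}),
    },
    flag_answers={l: False for l in DataTypeLabel},
)
d = diff_submission(result, submission).per_type[EntityType.GENE]
print(sorted(d.added), sorted(d.removed), d.jaccard)
```

```
['WBGene00002299'] [] 0.5
```

One entity added, none removed, gene Jaccard 0.5 for this paper.

## Command line

The `afp` command wraps the library: `afp extract`, `afp train`,
`afp classify`, `afp triage`, `afp remind`, `afp diff`, `afp stats`, and
`afp simulate {articles,corpus,submissions}` for synthetic fixtures.
Example batch run:

```
afp triage --articles articles.jsonl --lexicon-dir lexicons/ \
    --models models/ --registry registry.tsv --state state.json \
    --cap 50 --seed 7 --date 2019-10-02 --out report.json
```

All outputs are sorted-key JSON; a fixed seed yields byte-identical
reports.

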