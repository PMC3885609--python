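# rpe — reverse pathway engineering toolkit

Predicts how a target metabolite can be synthesized from known precursors by
applying biotransformation rules *backwards*, and proposes enzymes for the
predicted steps by phylogenetic ortholog inference.

The pipeline:

1. **Reaction database** (`rpe.db`): a TSV of atom-mapped reaction SMILES with
   reversibility flags and enzyme annotations is loaded, balance-checked,
   deduplicated by direction-aware canonical keys and indexed.
2. **Rule extraction** (`rpe.rules`): for every reaction the reaction center
   (bonds broken/formed/order-changed plus atoms with changed hydrogen count
   or charge) is detected from the atom maps; a directed rewrite rule with a
   configurable environment radius (default 1 bond) is extracted — two rules
   for reversible reactions, one otherwise.
3. **Retrosynthesis** (`rpe.search`): all rules are retro-applied to the
   target; each substructure match yields a complete, stoichiometrically
   balanced candidate reaction (missing co-products added, co-substrates
   copied verbatim). Candidates are ranked by presence of reactants and of the
   whole reaction in the database, structural simplicity, and cofactor
   frequency as a tie layer; the top candidates are expanded iteratively until
   a known precursor is reached. Routes are extracted, deduplicated and
   replayed forward for verification. Candidates absent from the database are
   flagged *novel* — these are the interesting predictions.
4. **Enzyme assignment** (`rpe.enzymes`, `rpe.phylo`): candidate enzymes come
   from the reference reaction and from database reactions sharing the same
   center chemistry; a bootstrapped neighbor-joining gene tree over homolog
   sequences is labeled with duplication/speciation events (species-overlap
   rule after midpoint rooting) and queried for orthologs in a target species.

`rpe.fixtures` regenerates, deterministically and offline, a fully
atom-mapped, exactly balanced branched-chain/sulfur amino-acid catabolism
network (19 reactions, including the chemical KMBA→MTAC oxidation and
methylation reference chemistry) plus simulated protein families with known
gene trees, so the whole pipeline is testable without external data.

## CLI

```bash
# regenerate the fixture reaction database
rpe fixture --name flavor-network --out db.tsv

# extract transformation rules (radius 1 environment)
rpe build-rules --db db.tsv --radius 1 --out rules.json

# retrosynthesize 3-methylbutanol back to leucine
echo "CC(C)CC(N)C(=O)O" > precursors.txt
rpe retro --target "CC(C)CCO" --db db.tsv --precursors precursors.txt \
    --radius 1 --max-depth 4 --beam 5 --out tree.json

# candidate reactions + enzymes for a target
rpe enzymes --db db.tsv --target "CSC" --out dms.json

# simulated protein family, bootstrapped NJ tree, ortholog verdict
rpe fixture --name protein-family --out fam.faa --seed 42
rpe orthologs --fasta fam.faa --species-map fam.species.tsv \
    --bootstrap 1000 --seed 42 --seed-leaf lox1_lpl \
    --target-species sth --out fam.nwk
```

All structured outputs are JSON stamped with the run configuration and tool
version; trees are written as Newick with bootstrap supports as internal
labels and event labels as NHX tags (`[&&NHX:Ev=D]` / `Ev=S`). Exit codes:
0 success, 2 validation error, 3 I/O error. A YAML config file
(`--config`) can mirror any flag; explicit flags win.

Note: by default the iterative search only recurses through proposed
precursors that occur in the reaction database (novel candidates are still
generated and flagged at every node); pass `--expand-unknown` to iterate
through never-seen structures as well.

## Layout

```
src/rpe/chem.py      molecules, reactions, balance, canonical keys
src/rpe/db.py        reaction TSV I/O, dedup, queries
src/rpe/rules.py     reaction centers, rule extraction, retro application
src/rpe/search.py    ranking, retro tree search, route extraction/replay
src/rpe/enzymes.py   candidate enzyme listing
src/rpe/phylo.py     p-distances, NJ, bootstrap, event labels, orthologs
src/rpe/fixtures.py  deterministic reaction network + family simulator
src/rpe/cli.py       command-line interface
```
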