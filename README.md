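# cysmsa

Toolkit for structure prediction pipelines around small cysteine-rich
proteins and their receptor complexes:

* **Cysteine-anchored MSA construction** — connectivity catalogs,
  barcode/debarcode transforms (assigned cysteines swapped for rare
  placeholder letters so external aligners cannot mispair them), a
  self-contained anchor-constrained aligner (center-star per inter-anchor
  segment), and incremental MSA augmentation via pairwise alignment.
* **MSA depth profiling** — per-position effective sequence count (Neff)
  at a configurable identity threshold.
* **Paired complex a3m assembly** — the three-block a3m dialect used for
  cognate receptor–ligand complex prediction (paired block + two gap-padded
  single-chain blocks under a `#L1,L2<TAB>1,1` header), plus
  template-guided refinement-job construction.
* **Model evaluation** — PDB/mmCIF parsing with per-residue confidence in
  the B-factor column, mean pLDDT ranking, pDockQ / pDockQ2 (constants from
  the published reference implementations, configurable), interchain
  heavy-atom contact counts, disulfide-bond detection and connectivity
  classification, and Kabsch-superposition RMSD to a reference with
  chain-pairing minimization.
* **Offline fixtures** — deterministic generators for cysteine-rich
  sequence families (with ground-truth anchor assignments) and toy dimer
  structures with planted contacts, disulfides, pLDDT, and PAE.

Structure prediction itself (running any network) is out of scope; this
package prepares inputs for predictors and evaluates their outputs.

## Test

```sh
python -m pytest -q tests/
```

The suite is fully offline and runs in a few seconds. Four optional tests
check mean-pLDDT values of deposited models from the published archive
(Zenodo record 8047768); they are skipped unless `CYSMSA_DEPOSITED_DIR`
points to a local extracted copy of that archive.

## CLI

Every pipeline stage is exposed as a `cysmsa` subcommand
(`barcode`, `debarcode`, `anchor-align`, `merge`, `neff`, `pair-msa`,
`promote`, `refine-job`, `eval-plddt`, `eval-pdockq`, `eval-pdockq2`,
`eval-rmsd`, `eval-contacts`, `ssbond`, `classify`, `fixtures`).
Exit codes: 0 success, 1 validation error, 2 usage error. Examples:

```sh
# synthetic 20-sequence family, anchor alignment, depth profile
cysmsa fixtures family --seed 1 --n 20 --n-cys 8 --out-fasta fam.fasta
cysmsa anchor-align --fasta fam.fasta --out fam.aln
cysmsa neff --msa fam.aln --threshold 0.8 --out fam.neff.tsv

# paired complex a3m from a cognate-pair manifest (label, receptor, ligand)
cysmsa pair-msa --pairs pairs.tsv --receptor esrk.aln --ligand sp11.aln \
    --query S8 --out complex.a3m

# model evaluation
cysmsa eval-plddt --model model.pdb
cysmsa eval-pdockq2 --model model.pdb --pae pae.json
cysmsa classify --model model.pdb          # disulfide connectivity
cysmsa eval-rmsd --model model.pdb --reference ref.pdb \
    --chain-map A:A,B:B,C:C,D:D --chain-map A:B,B:A,C:D,D:C
```

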