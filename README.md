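# cadherlink

Analysis toolkit for the extracellular machinery of intermicrovillar-link
cadherins — the PCDH24–CDHR5 adhesion system that connects adjacent
enterocyte microvilli (the gut's analog of the inner ear's CDH23–PCDH15
tip link). It is written for structural bioinformaticians and biophysicists
who work with tandem EC-repeat ectodomains and want one tested place to:

* **segment** processed cadherin sequences into EC repeats at
  DXNDN-class boundaries and **classify each inter-repeat linker's
  calcium stoichiometry** from the motif grammar
  `NTerm–XEX–DXD–D(R/Y)(D/E)–XDX–DXNDN–CTerm` (canonical → 3 Ca²⁺;
  site-1-degenerate/DXPDL-variant noncanonical → 2 Ca²⁺; degenerate →
  ≤1), plus tip site-0, disulfide-candidate and N-glycosylation-sequon
  annotation;
* **profile conservation** across species families: affine-gap global
  alignment (BLOSUM62, open 10, extend 0.5), percent identity under
  three normalizations, per-repeat identity profiles, progressive MSA
  over a UPGMA guide tree, 1–9 conservation grades;
* **quantify crystal structures**: Shrake–Rupley SASA, PISA-convention
  buried interface areas `(SASA_A + SASA_B − SASA_AB)/2` with the 856 Å²
  relevance threshold and >30% buried-fraction interface residues,
  space-group symmetry expansion, Kabsch superposition RMSD,
  calcium-site/disulfide detection, principal-axis orientation
  projections;
* **model link lengths** from domain counts at 4.5 nm/domain, with exact
  inversion from an observed length to the implied tip overlap;
* **fit 1:1 Langmuir SPR kinetics** globally across an injection series
  (shared k_on, k_off, R_max; K_D = k_off/k_on) with reported, never
  silent, outlier exclusion;
* **quantify bead-aggregation micrographs** (Otsu threshold, 8-connected
  components, pixel areas, mean-of-means ± SEM replicate statistics);
* **generate synthetic data with exact ground truth** for every stage, so
  the whole pipeline is testable offline.

See `docs/methods.md` for the models, defaults and idealizations.

## Worked example

Annotate a three-repeat synthetic family and inspect the junctions:

```bash
$ cadherlink synth family --seed 4 --out fam/
$ cadherlink annotate --fasta fam/family.fasta --expected-repeats 3 --out ann
$ head -6 ann.sp00.gff
##gff-version 3
sp00  cadherlink  EC_repeat  1    106  .  .  .  index=1;boundary_motif=DVNDN;typical_length=True
sp00  cadherlink  EC_repeat  107  203  .  .  .  index=2;boundary_motif=DVNDN;typical_length=True
sp00  cadherlink  EC_repeat  204  309  .  .  .  index=3;boundary_motif=terminal;typical_length=True
sp00  cadherlink  linker     82   106  .  .  .  junction=1;classification=canonical;predicted_calcium_count=3
sp00  cadherlink  linker     179  203  .  .  .  junction=2;classification=canonical;predicted_calcium_count=3
```

Each repeat ends on the last residue of its DXNDN-class match; both
junctions carry the full acidic motif, so each is predicted to chelate
three calcium ions.

Link-length arithmetic for the heterophilic 10-domain + 4-domain link:

```bash
$ cadherlink linklen --a 10 --b 4 --overlap 0..3
overlap 0: 63 nm
overlap 1: 58.5 nm
overlap 2: 54 nm
overlap 3: 49.5 nm
```

Tip-to-tip the link reaches 63 nm; three overlapping domains bring it to
49.5 nm, bracketing the ~48 nm spacing measured between microvilli.

Fit a simulated injection series (seven analyte concentrations spanning
2–23.5 μM, 1 RU read noise) and recover the dissociation constant:

```bash
$ cadherlink synth spr --seed 1 --out spr/
$ cadherlink sprfit --csv spr/sensorgrams.csv
{
  "kon_per_M_s": 9914.005999200173,
  "koff_per_s": 0.1606912083356972,
  "Rmax_RU": 100.70287933211522,
  "KD_M": 1.6208504246281592e-05,
  "residual_rms_RU": 1.0030550266431026,
  "excluded_injections": []
}
```

The global 1:1 fit returns K_D ≈ 16.2 μM against a simulation truth of
16 μM (k_on 10⁴ M⁻¹s⁻¹, k_off 0.16 s⁻¹), with no injection excluded.

The same operations are available as library calls
(`cadherlink.sequence_annotation.classify_linker`,
`cadherlink.structure_analysis.interface_area`,
`cadherlink.binding_kinetics.fit_kinetics`, …), and
`cadherlink run --config pipeline.yaml` chains stages with a content-hash
manifest so reruns are byte-reproducible.

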