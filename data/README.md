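# Reference tables

Transcribed summary numbers from the published Holstein/Jersey dairy-cattle
study whose analysis chain this package mirrors.  They are inputs for
consistency checks of the reporting conventions (e.g. that r_GFBLUP − Δr
recovers one GBLUP baseline per trait, and the per-trait best-term Δr
averages), not quantities this package computes or fits to.

* `table1_within_breed.tsv` — top five feature terms per trait for
  within-Holstein GFBLUP: accuracy r, bias, Δr over GBLUP, H²_f, m_f.
* `table2_between_breed.tsv` — the same for Holstein→Jersey prediction.
* `gblup_baselines.tsv` — GBLUP baseline accuracy and bias per trait,
  within-breed and between-breed.
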