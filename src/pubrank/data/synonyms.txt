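# Minimal COVID-related synonym groups used for query expansion.
# One group per line, comma-separated; members trigger each other.
# Edit or replace via the pipeline config (synonyms: <path>).
covid-19, sars-cov-2, coronavirus
covid, covid-19
2019-ncov, sars-cov-2
ncov, coronavirus
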