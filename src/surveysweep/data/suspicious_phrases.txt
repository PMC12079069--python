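# One phrase per line; matched after normalization (case-fold, strip
# punctuation, collapse whitespace). Lines starting with '#' are ignored.
very friendly informative and caring
quite encouraging and satisfying
it's good
A magazine gauidiance
General body check up
good and helpful services
they are very good
nice experience overall
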