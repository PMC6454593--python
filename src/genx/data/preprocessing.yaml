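# Sentence boundary and tokenizer configuration.
#
# abbreviations: a terminal '.' ending one of these (case-insensitive) never
#   closes a sentence.
# protected_tokens: matched as single tokens before the generic word rule;
#   keeps slash/ampersand-joined abbreviations intact.
# bullet_markers: regexes that open a new sentence when preceded by
#   whitespace or start-of-text.
abbreviations:
  - e.g.
  - i.e.
  - etc.
  - vs.
  - approx.
  - ca.
  - dr.
  - mr.
  - mrs.
  - ms.
  - st.
  - no.
  - fig.
  - al.
protected_tokens:
  - msm/w
  - msw/m
  - m/f
  - m&f
  - ymsm
bullet_markers:
  - "[-•*]\\s+"
  - "\\d{1,2}[.)]\\s+"
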