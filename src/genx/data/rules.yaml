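# Gender mention lexicon and heuristic-rule parameters.
#
# The extractor is data-driven: mention features, composition behavior and
# verification scopes all live here so they can be edited without touching
# code. Features are lowercase; multiword features are matched token-wise,
# longest first.

lexicon:
  Male: [males, male, man, men, gay, gays, masculine]
  Female: [females, female, woman, women, lesbians, lesbian, les, feminine]
  Two_Gender: [m/f, m&f, both genders, two genders, two-gender, all genders, all-gender]
  Biological: [biologically, biological, cisgender]
  Transgender: [transgender, transsexual, transsexuals, transsexualism, change sex,
                changed sex, sex changed, change gender, changed gender, gender changed,
                transgendered]
  Male_Abbreviation: [msm, msw, msm/w, msw/m, ymsm]
  Partner: [partner, partners, sexual partner, sexual partners, wife, husband]
  # "no" is quoted: bare no/yes are booleans in YAML 1.1
  Negation_Word: ["no", "not", except, besides, rather, rather than, neither,
                  not identify as, not identified as]

composition:
  # max tokens allowed between a Transgender/Biological qualifier and the
  # sex word it composes with ("transgender ... woman")
  qualifier_gap: 2

verification:
  # a Partner feature starting within this many tokens after a mention
  # makes it irrelevant ("male sex partners")
  partner_gap: 2
  # a negation trigger attaches to the nearest mention within this window,
  # preferring a following mention over a preceding one
  negation_window: 4

patterns:
  # pattern slots may span at most this many tokens
  slot_max: 10
  # context cues indicating the slot's sexed word is a gender identity over
  # an assigned sex at birth
  birth_cues: [at birth, assigned]

sections:
  inclusion_header: '(?i)inclusion\s+criteria\s*:?'
  exclusion_header: '(?i)exclusion\s+criteria\s*:?'
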