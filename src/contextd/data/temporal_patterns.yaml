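# Default historical-evidence patterns for the temporality module.
# window_tokens: either an integer or {left: n, right: m}; windows are counted
# in tokens outward from the mention and never cross the sentence boundary.
- id: status_na
  regex: \bstatus na\b
  side: left
  window_tokens: {left: 5, right: 3}
- id: duration_ago
  regex: \b(?P<num>\d+)\s*(?P<unit>dag|dagen|week|weken|maand|maanden|jaar|jaren)\s+geleden\b
  side: either
  window_tokens: {left: 5, right: 3}
  numeric_duration: true
  guard: '[<>]=?\s*\d'
- id: bare_duration
  regex: \b(?P<num>\d+)\s*(?P<unit>dag|dagen|week|weken|maand|maanden|jaar|jaren)\b
  side: either
  window_tokens: {left: 5, right: 3}
  numeric_duration: true
  guard: '[<>]=?\s*\d|\bnet\b|\brecent\b'
- id: sinds_duration
  regex: \bsinds\s+(?P<num>\d+)\s*(?P<unit>week|weken|maand|maanden|jaar|jaren)\b
  side: either
  window_tokens: {left: 5, right: 3}
  numeric_duration: true
- id: year_in
  regex: \bin\s+(?P<year>(?:19|20)\d{2})\b
  side: either
  window_tokens: {left: 5, right: 3}
  year_before_reference: true
- id: in_het_verleden
  regex: \bin het verleden\b
  side: either
  window_tokens: {left: 5, right: 3}
- id: als_kind
  regex: \bals kind\b
  side: either
  window_tokens: {left: 5, right: 3}
- id: voorgeschiedenis
  regex: \bvoorgeschiedenis\b
  side: left
  window_tokens: {left: 5, right: 3}
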