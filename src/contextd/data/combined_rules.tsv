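pre_phrase	post_phrase	property	value	max_span_tokens	doc_types
nooit	doorgemaakt	negation	Negated	10	*
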