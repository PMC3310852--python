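<?xml version="1.0" encoding="utf-8"?>
<ClaML version="2.0.0">
  <Title name="ICF-excerpt" version="2001">Discussion subtree</Title>
  <Class code="d3" kind="chapter">
    <SubClass code="d355" />
    <Rubric kind="preferred">
      <Label xml:lang="en">Communication</Label>
    </Rubric>
  </Class>
  <Class code="d355" kind="category">
    <SuperClass code="d3" />
    <SubClass code="d3550" />
    <SubClass code="d3551" />
    <Rubric kind="preferred">
      <Label xml:lang="en">Discussion</Label>
    </Rubric>
    <Rubric kind="definition">
      <Label xml:lang="en">Starting, sustaining and ending an examination of a matter, with arguments for or against, carried out by means of spoken, written, sign or other forms of language.</Label>
    </Rubric>
  </Class>
  <Class code="d3550" kind="category">
    <SuperClass code="d355" />
    <Rubric kind="preferred">
      <Label xml:lang="en">Discussion with one person</Label>
    </Rubric>
  </Class>
  <Class code="d3551" kind="category">
    <SuperClass code="d355" />
    <Rubric kind="preferred">
      <Label xml:lang="en">Discussion with many people</Label>
    </Rubric>
  </Class>
</ClaML>
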