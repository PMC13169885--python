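the
a
an
of
and
to
in
is
it
that
was
this
at
on
for
with
then
so
just
very
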