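# Default English stopword list used when filtering tokens before
# frequent-noun extraction. One token per line; lines starting with '#'
# are comments. Edit freely — the shipped list is a compact default,
# not a dataset-specific list.
a
an
and
are
as
at
be
been
but
by
can
could
did
do
does
for
from
had
has
have
he
her
him
his
i
if
in
is
it
its
just
me
my
no
not
of
on
or
our
she
so
that
the
their
them
they
this
to
up
us
was
we
were
what
when
which
who
will
with
would
you
your
yeah
yes
okay
ok
um
uh
oh
well
like
gonna
really
mhm
uh-huh
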