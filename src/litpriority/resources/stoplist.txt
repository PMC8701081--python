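# Default stop list, one lemma per line ('#' lines ignored).
# Applied AFTER lemmatization, so singular forms cover their plurals.
# Part 1: English function words.
a
about
above
after
again
against
all
also
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
did
do
doe
does
doing
down
during
each
few
for
from
further
had
ha
has
have
having
he
her
here
hers
herself
him
himself
his
how
however
i
if
in
into
is
it
its
itself
just
may
me
might
more
most
must
my
myself
no
nor
not
now
of
off
on
once
only
or
other
ought
our
ours
ourselves
out
over
own
same
she
should
shall
so
some
such
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
too
under
until
up
upon
very
wa
was
we
were
what
when
where
which
while
who
whom
why
will
with
within
without
would
you
your
yours
yourself
yourselves
# Part 2: scientific-article boilerplate.
abstract
aim
analysis
approach
article
author
background
conclusion
copyright
data
discussion
et
al
figure
finding
introduction
journal
keyword
literature
material
method
methodology
objective
paper
preprint
publication
publish
published
result
review
section
significance
studied
study
table
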